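"""TSV readers and writers for every table the pipeline consumes.

Dialects
--------
copy-number   rows = genes; first column the gene identifier
              (``gene_id`` or ``Hugo_Symbol``), remaining columns case
              ids; cells in {-2,-1,0,1,2} or blank/NA.
expression    same layout, non-negative reals.
gene location ``gene_id  chromosome  cytoband`` TSV (optionally
              ``start``/``end``, 1-based inclusive), or 4+-column BED
              (0-based half-open, converted on read; the 4th column is
              the gene id).
clinical      one row per case: ``case_id`` plus factor columns.
IHC           ``case_id  tissue  pct0  pct1  pct2  pct3``.

NA spellings "", "NA", "NaN", "nan", "null" are normalized on read;
write(read(x)) preserves content.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .arms import GeneLocation
from .burden import CnaBurden, GeneCopyMatrix, burden_frame
from .ihc import IhcRecord, IntensityDistribution

__all__ = [
    "load_copy_matrix",
    "load_expression",
    "load_gene_locations",
    "load_clinical",
    "load_ihc",
    "write_copy_matrix",
    "write_expression",
    "write_gene_locations",
    "write_clinical",
    "write_ihc",
    "write_burden",
    "write_summary",
    "write_bundle",
]

NA_VALUES = ["", "NA", "NaN", "nan", "null", "N/A"]
_GENE_ID_HEADERS = ("gene_id", "Hugo_Symbol", "gene", "symbol")


def _check_unique_header(path: Path) -> list[str]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    seen: set[str] = set()
    for col in header:
        if col in seen:
            raise ValueError(f"{path}: duplicate column {col!r} in header")
        seen.add(col)
    return header


def _read_gene_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    header = _check_unique_header(path)
    if header[0] not in _GENE_ID_HEADERS:
        raise ValueError(
            f"{path}: first column must be one of {_GENE_ID_HEADERS}, got {header[0]!r}"
        )
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=NA_VALUES, keep_default_na=False
    )
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene id(s): {dupes[:5]}")
    df.index.name = None  # header label is dialect, not content
    return df


def load_copy_matrix(path: str | Path) -> GeneCopyMatrix:
    """Read a gene × case discrete copy-number call matrix."""
    df = _read_gene_table(path)
    try:
        df = df.astype("Float64").astype("Int8")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-integer cell in copy-number matrix: {exc}") from exc
    return GeneCopyMatrix(df)


def load_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene × case expression matrix (non-negative reals)."""
    df = _read_gene_table(path)
    try:
        df = df.astype(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric cell in expression matrix: {exc}") from exc
    return df


def load_gene_locations(path: str | Path) -> list[GeneLocation]:
    """Read gene locations from a TSV (gene_id/chromosome/cytoband[/start/end])
    or a BED file (coordinates converted to 1-based inclusive)."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        out: list[GeneLocation] = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}:{ln}: BED needs >= 4 columns (name in col 4)")
                chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                out.append(
                    GeneLocation(
                        gene_id=name,
                        chromosome=chrom,
                        start=start + 1,  # 0-based half-open -> 1-based inclusive
                        end=end,
                    )
                )
        return out
    header = _check_unique_header(path)
    df = pd.read_csv(path, sep="\t", na_values=NA_VALUES, keep_default_na=False, dtype=str)
    required = {"gene_id", "chromosome"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: gene-location TSV needs columns {sorted(required)}")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            GeneLocation(
                gene_id=str(d["gene_id"]),
                chromosome=str(d["chromosome"]),
                cytoband=d.get("cytoband") if pd.notna(d.get("cytoband")) else None,
                start=int(d["start"]) if d.get("start") and pd.notna(d.get("start")) else None,
                end=int(d["end"]) if d.get("end") and pd.notna(d.get("end")) else None,
            )
        )
    return out


def load_clinical(path: str | Path) -> pd.DataFrame:
    """Read a per-case clinical table; first column must be case_id."""
    path = Path(path)
    header = _check_unique_header(path)
    if header[0] != "case_id":
        raise ValueError(f"{path}: first clinical column must be 'case_id'")
    df = pd.read_csv(path, sep="\t", na_values=NA_VALUES, keep_default_na=False)
    if df.empty:
        raise ValueError(f"{path}: clinical table is empty")
    if df["case_id"].duplicated().any():
        dupes = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
        raise ValueError(f"{path}: duplicate case id(s): {dupes[:5]}")
    return df


def load_ihc(path: str | Path) -> list[IhcRecord]:
    """Read per-case staining-intensity distributions."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=NA_VALUES, keep_default_na=False)
    needed = {"case_id", "tissue", "pct0", "pct1", "pct2", "pct3"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: IHC TSV needs columns {sorted(needed)}")
    records = []
    for row in df.itertuples(index=False):
        dist = IntensityDistribution([row.pct0, row.pct1, row.pct2, row.pct3])
        records.append(IhcRecord(str(row.case_id), str(row.tissue), dist))
    return records


def write_copy_matrix(matrix: GeneCopyMatrix, path: str | Path) -> None:
    matrix.calls.to_csv(path, sep="\t", index_label="gene_id", na_rep="NA")


def write_expression(expression: pd.DataFrame, path: str | Path) -> None:
    expression.to_csv(path, sep="\t", index_label="gene_id", na_rep="NA")


def write_gene_locations(locations: Sequence[GeneLocation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [l.gene_id for l in locations],
            "chromosome": [l.chromosome for l in locations],
            "cytoband": [l.cytoband or "" for l in locations],
            "start": [l.start if l.start is not None else "" for l in locations],
            "end": [l.end if l.end is not None else "" for l in locations],
        }
    ).to_csv(path, sep="\t", index=False)


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_ihc(records: Sequence[IhcRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        p0, p1, p2, p3 = r.distribution.percent_at
        rows.append(
            {"case_id": r.case_id, "tissue": r.tissue,
             "pct0": p0, "pct1": p1, "pct2": p2, "pct3": p3,
             "score": r.score, "label": r.label}
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_burden(burdens: Sequence[CnaBurden], path: str | Path) -> None:
    burden_frame(burdens).to_csv(path, sep="\t", index=False)


def write_summary(summary: dict, path: str | Path) -> None:
    """Machine-readable run summary (JSON)."""
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_bundle(bundle, out_dir: str | Path) -> dict[str, Path]:
    """Write every table of a synthetic cohort bundle into ``out_dir``;
    returns the paths written, keyed by table name."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "copy_number": out / "copy_number.tsv",
        "expression": out / "expression.tsv",
        "gene_locations": out / "gene_locations.tsv",
        "clinical": out / "clinical.tsv",
        "ihc": out / "ihc.tsv",
        "truth": out / "truth.tsv",
    }
    write_copy_matrix(bundle.copy_matrix, paths["copy_number"])
    write_expression(bundle.expression, paths["expression"])
    write_gene_locations(bundle.gene_locations, paths["gene_locations"])
    write_clinical(bundle.clinical, paths["clinical"])
    write_ihc(bundle.ihc, paths["ihc"])
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
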