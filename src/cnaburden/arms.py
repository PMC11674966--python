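"""Chromosome-arm universe and gene-to-arm mapping.

Gene-level copy-number calls are aggregated per chromosome arm, so the
first step of the pipeline is a deterministic map from gene identifiers
to arms.  The default arm universe holds the 39 non-acrocentric autosomal
arms plus Xp/Xq: the p arms of the acrocentric chromosomes (13, 14, 15,
21, 22) carry essentially no protein-coding genes in gene-level call
tables, which would make a fractional calling rule vacuous there, and Y
is excluded by default.  The full 48-arm set can be selected through
:class:`ArmUniverseConfig`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import total_ordering
from typing import Iterable, Mapping

__all__ = [
    "ArmId",
    "GeneLocation",
    "ArmUniverseConfig",
    "ArmMap",
    "build_arm_map",
    "genes_on_arm",
    "parse_arm_from_cytoband",
    "DEFAULT_ARM_UNIVERSE",
]

_CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
_CHROM_ORDER: dict[str, int] = {c: i for i, c in enumerate(_CHROMOSOMES)}
ACROCENTRIC: frozenset[str] = frozenset({"13", "14", "15", "21", "22"})


@total_ordering
@dataclass(frozen=True)
class ArmId:
    """One chromosome arm, e.g. ``ArmId("17", "p")`` == "17p".

    Ordering is genomic: 1p, 1q, 2p, ..., 22q, Xp, Xq, Yp, Yq.
    """

    chromosome: str
    arm: str

    def __post_init__(self) -> None:
        chrom = str(self.chromosome).removeprefix("chr").upper()
        chrom = chrom.removesuffix(".0") if chrom.endswith(".0") else chrom
        if chrom not in _CHROM_ORDER:
            raise ValueError(f"unknown chromosome: {self.chromosome!r}")
        if self.arm not in ("p", "q"):
            raise ValueError(f"arm must be 'p' or 'q', got {self.arm!r}")
        object.__setattr__(self, "chromosome", chrom)

    @classmethod
    def parse(cls, text: str) -> "ArmId":
        m = re.fullmatch(r"(chr)?([0-9]{1,2}|X|Y)([pq])", str(text).strip(), re.IGNORECASE)
        if not m:
            raise ValueError(f"cannot parse arm id: {text!r}")
        return cls(m.group(2).upper(), m.group(3).lower())

    def __str__(self) -> str:
        return f"{self.chromosome}{self.arm}"

    def _key(self) -> tuple[int, int]:
        return (_CHROM_ORDER[self.chromosome], 0 if self.arm == "p" else 1)

    def __lt__(self, other: "ArmId") -> bool:
        if not isinstance(other, ArmId):
            return NotImplemented
        return self._key() < other._key()


def parse_arm_from_cytoband(chromosome: str, cytoband: str) -> ArmId | None:
    """Extract the arm from a cytoband label such as ``17p13.1``.

    The chromosome may be repeated in the band label or absent from it;
    returns None for unparseable or unplaced band strings.
    """
    band = str(cytoband).strip()
    m = re.match(r"(?:chr)?([0-9]{1,2}|X|Y)?\s*([pq])", band, re.IGNORECASE)
    if not m:
        return None
    chrom = m.group(1) or str(chromosome).removeprefix("chr")
    try:
        return ArmId(str(chrom).upper(), m.group(2).lower())
    except ValueError:
        return None


@dataclass(frozen=True)
class GeneLocation:
    """Location of one gene: chromosome plus either a cytoband string or
    1-based inclusive start/end coordinates (BED input is converted on read)."""

    gene_id: str
    chromosome: str
    cytoband: str | None = None
    start: int | None = None
    end: int | None = None
    arm: ArmId | None = None

    def resolve_arm(self) -> ArmId | None:
        if self.arm is not None:
            return self.arm
        if self.cytoband:
            return parse_arm_from_cytoband(self.chromosome, self.cytoband)
        return None


def _default_universe() -> tuple[ArmId, ...]:
    arms: list[ArmId] = []
    for chrom in tuple(str(i) for i in range(1, 23)) + ("X",):
        for pq in ("p", "q"):
            if pq == "p" and chrom in ACROCENTRIC:
                continue
            arms.append(ArmId(chrom, pq))
    return tuple(arms)


DEFAULT_ARM_UNIVERSE: tuple[ArmId, ...] = _default_universe()


@dataclass(frozen=True)
class ArmUniverseConfig:
    """Which arms participate in burden counting.

    ``include_acrocentric_p`` and ``include_y`` extend the default
    41-arm universe (39 autosomal arms + Xp/Xq) to the full 48-arm set.
    An explicit ``arms`` sequence overrides both flags.
    """

    include_acrocentric_p: bool = False
    include_x: bool = True
    include_y: bool = False
    arms: tuple[ArmId, ...] | None = None

    def universe(self) -> tuple[ArmId, ...]:
        if self.arms is not None:
            if not self.arms:
                raise ValueError("arm universe is empty")
            return tuple(sorted(set(self.arms)))
        out: list[ArmId] = []
        chroms = list(str(i) for i in range(1, 23))
        if self.include_x:
            chroms.append("X")
        if self.include_y:
            chroms.append("Y")
        for chrom in chroms:
            for pq in ("p", "q"):
                if (
                    pq == "p"
                    and chrom in ACROCENTRIC
                    and not self.include_acrocentric_p
                ):
                    continue
                out.append(ArmId(chrom, pq))
        if not out:
            raise ValueError("arm universe is empty")
        return tuple(sorted(out))


@dataclass
class ArmMap:
    """Gene → arm assignment over a fixed, ordered arm universe.

    Every mapped gene lies on exactly one arm inside the universe; genes
    whose location could not be resolved, or whose arm falls outside the
    universe, are listed in ``unmapped``.
    """

    arm_universe: tuple[ArmId, ...]
    gene_to_arm: dict[str, ArmId]
    unmapped: tuple[str, ...] = ()
    # per-gene sort key for deterministic within-arm order (position, id)
    _gene_order: dict[str, tuple[float, str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        universe = set(self.arm_universe)
        for gene, arm in self.gene_to_arm.items():
            if arm not in universe:
                raise ValueError(f"gene {gene!r} maps to arm {arm} outside the universe")

    @property
    def n_mapped(self) -> int:
        return len(self.gene_to_arm)

    def genes_on(self, arm: ArmId) -> tuple[str, ...]:
        return genes_on_arm(self, arm)

    def mapping_report(self) -> dict[str, int]:
        per_arm = {str(a): 0 for a in self.arm_universe}
        for arm in self.gene_to_arm.values():
            per_arm[str(arm)] += 1
        return {
            "n_genes_mapped": self.n_mapped,
            "n_genes_unmapped": len(self.unmapped),
            **{f"arm_{a}": n for a, n in per_arm.items()},
        }


def build_arm_map(
    locations: Iterable[GeneLocation | Mapping],
    config: ArmUniverseConfig | None = None,
) -> ArmMap:
    """Assign each gene to one chromosome arm.

    Parameters
    ----------
    locations
        Gene locations; mappings with keys ``gene_id``/``chromosome`` and
        optionally ``cytoband``/``start``/``end`` are accepted.
    config
        Arm-universe configuration; the default excludes acrocentric
        p-arms and Y.

    Raises
    ------
    ValueError
        If ``locations`` is empty, or a gene appears twice with
        conflicting arms.
    """
    config = config or ArmUniverseConfig()
    universe = config.universe()
    universe_set = set(universe)

    locs: list[GeneLocation] = []
    for loc in locations:
        if not isinstance(loc, GeneLocation):
            loc = GeneLocation(
                gene_id=str(loc["gene_id"]),
                chromosome=str(loc["chromosome"]),
                cytoband=loc.get("cytoband"),
                start=loc.get("start"),
                end=loc.get("end"),
            )
        locs.append(loc)
    if not locs:
        raise ValueError("no gene locations provided")

    gene_to_arm: dict[str, ArmId] = {}
    gene_order: dict[str, tuple[float, str]] = {}
    unmapped: set[str] = set()
    # sort input so the result is independent of row order
    for loc in sorted(locs, key=lambda l: l.gene_id):
        arm = loc.resolve_arm()
        if arm is None or arm not in universe_set:
            if loc.gene_id not in gene_to_arm:
                unmapped.add(loc.gene_id)
            continue
        prev = gene_to_arm.get(loc.gene_id)
        if prev is not None and prev != arm:
            raise ValueError(
                f"gene {loc.gene_id!r} listed on conflicting arms {prev} and {arm}"
            )
        gene_to_arm[loc.gene_id] = arm
        unmapped.discard(loc.gene_id)
        pos = float(loc.start) if loc.start is not None else float("inf")
        gene_order[loc.gene_id] = min(
            gene_order.get(loc.gene_id, (float("inf"), loc.gene_id)),
            (pos, loc.gene_id),
        )

    return ArmMap(
        arm_universe=universe,
        gene_to_arm=gene_to_arm,
        unmapped=tuple(sorted(unmapped)),
        _gene_order=gene_order,
    )


def genes_on_arm(arm_map: ArmMap, arm: ArmId | str) -> tuple[str, ...]:
    """Genes assigned to ``arm``, ordered by genomic position when known
    and lexicographically otherwise."""
    if isinstance(arm, str):
        arm = ArmId.parse(arm)
    if arm not in set(arm_map.arm_universe):
        raise ValueError(f"arm {arm} is not in the configured arm universe")
    genes = [g for g, a in arm_map.gene_to_arm.items() if a == arm]
    genes.sort(key=lambda g: arm_map._gene_order.get(g, (float("inf"), g)))
    return tuple(genes)
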