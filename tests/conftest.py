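from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cnaburden import ArmId, GeneCopyMatrix, build_arm_map

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def small_arm_map():
    """Two-arm map: 3 genes on 17p, 2 on 17q."""
    locs = [
        {"gene_id": f"P{i}", "chromosome": "17", "cytoband": "17p13"} for i in range(3)
    ] + [
        {"gene_id": f"Q{i}", "chromosome": "17", "cytoband": "17q21"} for i in range(2)
    ]
    return build_arm_map(locs)


def random_small_matrix(rng: np.random.Generator):
    """A random gene×case call matrix over ≤5 arms, ≤8 genes/arm,
    ≤10 cases, with missing cells; returns (GeneCopyMatrix, gene→arm,
    arm labels, cells dict) for oracle recounting."""
    n_arms = rng.integers(1, 6)
    arms = [str(a) for a in
            [ArmId(str(c), pq) for c in range(1, 13) for pq in ("p", "q")][:n_arms]]
    gene_to_arm: dict[str, str] = {}
    for arm in arms:
        for i in range(rng.integers(1, 9)):
            gene_to_arm[f"g{arm}_{i}"] = arm
    genes = list(gene_to_arm)
    n_cases = int(rng.integers(1, 11))
    cases = [f"c{i}" for i in range(n_cases)]
    values = rng.choice([-2, -1, 0, 1, 2], size=(len(genes), n_cases))
    missing = rng.random((len(genes), n_cases)) < 0.15
    cells = {
        (g, c): (None if missing[i, j] else int(values[i, j]))
        for i, g in enumerate(genes)
        for j, c in enumerate(cases)
    }
    df = pd.DataFrame(
        np.where(missing, np.nan, values), index=genes, columns=cases
    ).astype("Float64").astype("Int8")
    locs = [
        {"gene_id": g, "chromosome": arm[:-1], "cytoband": arm + "11"}
        for g, arm in gene_to_arm.items()
    ]
    return GeneCopyMatrix(df), gene_to_arm, arms, cases, cells, locs
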