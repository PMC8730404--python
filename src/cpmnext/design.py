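"""Enumeration of the simulation study's factorial design.

The study crosses 35 replicate landscapes with 2 gene counts (7, 10),
3 fitness-landscape types, 3 initial population sizes and 2 mutation-rate
regimes — 1260 landscape configurations — and then samples each under
3 detection regimes, 3 sample sizes and 5 non-overlapping splits, for
56700 data-set configurations.
"""

from __future__ import annotations

import itertools

import pandas as pd

from .evolsim import POPULATION_SIZES
from .sampling import DETECTION_REGIMES, N_SPLITS, SAMPLE_SIZES

__all__ = ["landscape_grid", "dataset_grid"]

GENE_COUNTS = (7, 10)
LANDSCAPE_KINDS = ("representable", "local_maxima", "rmf")
MU_REGIMES = ("fixed", "loguniform")
N_REPLICATES = 35


def landscape_grid(
    replicates: int = N_REPLICATES,
    gene_counts=GENE_COUNTS,
    kinds=LANDSCAPE_KINDS,
    pop_sizes=POPULATION_SIZES,
    mu_regimes=MU_REGIMES,
) -> pd.DataFrame:
    """One row per landscape configuration (default: the study's 1260)."""
    rows = [
        {
            "replicate": r,
            "genes": g,
            "landscape_kind": k,
            "pop_size": n,
            "mu_regime": m,
        }
        for r, g, k, n, m in itertools.product(
            range(replicates), gene_counts, kinds, pop_sizes, mu_regimes
        )
    ]
    return pd.DataFrame(rows)


def dataset_grid(
    landscapes: pd.DataFrame | None = None,
    detection_regimes=DETECTION_REGIMES,
    sample_sizes=SAMPLE_SIZES,
    n_splits: int = N_SPLITS,
    **landscape_kwargs,
) -> pd.DataFrame:
    """One row per sampled data set (default: the study's 56700)."""
    if landscapes is None:
        landscapes = landscape_grid(**landscape_kwargs)
    ext = pd.DataFrame(
        [
            {"detect": d, "sample_size": s, "split": k}
            for d, s, k in itertools.product(
                detection_regimes, sample_sizes, range(n_splits)
            )
        ]
    )
    return landscapes.merge(ext, how="cross")
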