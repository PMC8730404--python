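"""Cross-sectional sampling of simulated tumors and real-data input.

Each simulated process contributes one *observation*: the majority
genotype at a sampled snapshot.  Three detection regimes weight the choice
of snapshot by tumor size: ``uniform`` weights all snapshots equally;
``small`` is enriched in early (small-tumor) snapshots with weight
``(1 - r)^2`` and ``large`` in late (large-tumor) snapshots with weight
``r^2``, where ``r`` is the within-run percentile rank of total
population size.  No sampling error is applied: the observation equals
the majority genotype exactly.

Real cross-sectional data enter as CSV binary matrices (header of gene
names, rows = tumors, cells strictly 0/1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .landscapes import genotype_str
from .evolsim import EvolutionRun

__all__ = [
    "DETECTION_REGIMES",
    "SAMPLE_SIZES",
    "N_SPLITS",
    "CrossSectionalSample",
    "sample_observation",
    "build_cross_sectional",
    "make_splits",
    "select_top_features",
    "read_binary_matrix",
]

DETECTION_REGIMES = ("uniform", "small", "large")
SAMPLE_SIZES = (50, 200, 4000)
N_SPLITS = 5


@dataclass
class CrossSectionalSample:
    """A binary mutation matrix: rows = tumors, columns = genes."""

    matrix: pd.DataFrame
    regime: str = "uniform"
    source_run_ids: Sequence[int] | None = None
    split_id: int | None = None

    def __post_init__(self) -> None:
        vals = self.matrix.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("matrix entries must be 0 or 1")

    @property
    def G(self) -> int:
        return self.matrix.shape[1]

    def genotype_ints(self) -> np.ndarray:
        bits = self.matrix.to_numpy(dtype=np.int64)
        return bits @ (1 << np.arange(self.G, dtype=np.int64))

    def to_csv(self, path) -> None:
        self.matrix.to_csv(path, index=False)


def _snapshot_weights(totals: np.ndarray, regime: str) -> np.ndarray:
    n = len(totals)
    if regime not in DETECTION_REGIMES:
        raise ValueError(f"unknown detection regime {regime!r}")
    if regime == "uniform" or n == 1:
        return np.full(n, 1.0 / n)
    ranks = rankdata(totals, method="average")
    r = (ranks - 1.0) / (n - 1.0)
    w = (1.0 - r) ** 2 if regime == "small" else r**2
    if w.sum() == 0:  # degenerate (constant sizes collapse to uniform anyway)
        w = np.full(n, 1.0)
    return w / w.sum()


def sample_observation(run: EvolutionRun, regime: str, seed=None) -> int:
    """Draw one observation (majority genotype at a size-weighted snapshot)."""
    snaps = [s for s in run.history if s.counts]
    if not snaps:
        raise ValueError("run has no non-empty snapshots")
    totals = np.array([s.total for s in snaps], dtype=float)
    w = _snapshot_weights(totals, regime)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(snaps), p=w)
    return snaps[idx].majority()


def build_cross_sectional(
    runs: Sequence[EvolutionRun],
    regime: str,
    seed=None,
    n_obs: int | None = None,
    gene_names: Sequence[str] | None = None,
) -> CrossSectionalSample:
    """One observation per run (the study's scheme), as a binary matrix.

    When ``n_obs`` exceeds the number of runs, source runs are drawn with
    replacement so that reduced-scale simulations can still power the
    larger sample sizes; each drawn observation re-samples its snapshot
    independently.
    """
    runs = [r for r in runs if r.history]
    if not runs:
        raise ValueError("no runs to sample from")
    G = runs[0].G
    rng = np.random.default_rng(seed)
    if n_obs is None:
        run_ids = np.arange(len(runs))
    elif n_obs <= len(runs):
        run_ids = rng.permutation(len(runs))[:n_obs]
    else:
        run_ids = rng.integers(0, len(runs), size=n_obs)
    rows = np.empty((len(run_ids), G), dtype=np.int8)
    for k, rid in enumerate(run_ids):
        g = sample_observation(runs[rid], regime, seed=rng.integers(2**31))
        rows[k] = [(g >> i) & 1 for i in range(G)]
    if gene_names is None:
        gene_names = [f"g{i + 1}" for i in range(G)]
    return CrossSectionalSample(
        matrix=pd.DataFrame(rows, columns=list(gene_names)),
        regime=regime,
        source_run_ids=list(map(int, run_ids)),
    )


def make_splits(
    full_sample: CrossSectionalSample, size: int, k: int = N_SPLITS, seed=None
) -> list[CrossSectionalSample]:
    """``k`` pairwise-disjoint row subsets of ``size`` rows each."""
    n = len(full_sample.matrix)
    if k * size > n:
        raise ValueError(f"cannot draw {k} disjoint splits of {size} rows from {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    out = []
    src = full_sample.source_run_ids
    for s in range(k):
        idx = np.sort(perm[s * size : (s + 1) * size])
        out.append(
            CrossSectionalSample(
                matrix=full_sample.matrix.iloc[idx].reset_index(drop=True),
                regime=full_sample.regime,
                source_run_ids=None if src is None else [src[i] for i in idx],
                split_id=s,
            )
        )
    return out


def select_top_features(
    matrix: pd.DataFrame, k: int = 15
) -> tuple[pd.DataFrame, list[str]]:
    """Keep the ``k`` most frequently mutated columns (ties: column order)."""
    if k > matrix.shape[1]:
        raise ValueError("k exceeds the number of columns")
    freq = matrix.to_numpy().mean(axis=0)
    order = np.argsort(-freq, kind="stable")[:k]
    order = np.sort(order)  # preserve original column order among the kept
    kept = [matrix.columns[i] for i in order]
    return matrix[kept].copy(), kept


def read_binary_matrix(path) -> CrossSectionalSample:
    """Read a user-supplied cross-sectional CSV (strict 0/1, no missing)."""
    df = pd.read_csv(path)
    if df.isna().any().any():
        raise ValueError("missing values are not allowed in binary mutation matrices")
    return CrossSectionalSample(matrix=df.astype(int))
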