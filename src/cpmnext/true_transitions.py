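"""Ground-truth conditional transition probabilities from simulated runs.

The truth matrix **P** answers: *given that genotype i (n mutations) has
been observed, what genotype with n + 1 mutations is in the Line of
Descent?*  For every fixated run and every genotype observed in it
(i.e. majority at some snapshot):

* if the LOD's (n+1)-mutation genotype is a superset of i, that run
  credits the transition i -> j;
* if i is the fixated genotype, or carries at least as many mutations as
  the fixated genotype, the run credits the NONE outcome ("no genotype
  comes next");
* otherwise the LOD continued through a different lineage; by default the
  run is excluded from row i's denominator so that truth and model
  predictions share the superset-plus-NONE support (the excluded mass is
  reported per row as ``other_lineage_fraction``); alternatively such runs
  may be counted toward NONE.

Row probabilities are exact ratios of integer counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .landscapes import genotype_str, n_mutations, one_mutation_supersets
from .evolsim import EvolutionRun

__all__ = ["NONE_OUTCOME", "row_support", "TransitionTable", "true_transition_table"]

#: Sentinel outcome for "no genotype comes next".
NONE_OUTCOME = "NONE"


def row_support(i: int, G: int) -> list:
    """Outcome list for an observed genotype: its one-mutation supersets in
    gene order, then NONE."""
    return [*one_mutation_supersets(i, G), NONE_OUTCOME]


@dataclass
class TransitionTable:
    """Per observed genotype, a distribution over next-step outcomes.

    ``rows[i]`` maps each outcome in ``row_support(i, G)`` to its
    probability.  For truth tables, ``counts`` and ``denominators`` keep
    the underlying integers and ``other_lineage_fraction`` the share of
    observations excluded because the LOD continued through a lineage not
    containing ``i``.  ``flags`` marks rows produced by fallback rules.
    """

    G: int
    rows: dict[int, dict]
    counts: dict[int, dict] = field(default_factory=dict)
    denominators: dict[int, int] = field(default_factory=dict)
    other_lineage_fraction: dict[int, float] = field(default_factory=dict)
    flags: dict[int, str] = field(default_factory=dict)

    def genotypes(self) -> list[int]:
        return sorted(self.rows)

    def row_vector(self, i: int) -> np.ndarray:
        """Probabilities aligned to ``row_support(i, G)``."""
        row = self.rows[i]
        return np.array([row.get(o, 0.0) for o in row_support(i, self.G)])

    def validate(self, atol: float = 1e-9) -> None:
        for i, row in self.rows.items():
            support = set(row_support(i, self.G))
            if not set(row) <= support:
                raise ValueError(f"row {genotype_str(i, self.G)} has outcomes off support")
            if any(p < -atol for p in row.values()):
                raise ValueError("negative probability")
            if abs(sum(row.values()) - 1.0) > atol:
                raise ValueError(f"row {genotype_str(i, self.G)} does not sum to 1")

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i in self.genotypes():
            for o in row_support(i, self.G):
                recs.append(
                    {
                        "observed_genotype": genotype_str(i, self.G),
                        "outcome": o if o == NONE_OUTCOME else genotype_str(o, self.G),
                        "probability": self.rows[i].get(o, 0.0),
                        "count": self.counts.get(i, {}).get(o, np.nan),
                        "denominator": self.denominators.get(i, np.nan),
                        "other_lineage_fraction": self.other_lineage_fraction.get(i, np.nan),
                        "flag": self.flags.get(i, ""),
                    }
                )
        return pd.DataFrame(recs)


def true_transition_table(
    runs: Sequence[EvolutionRun],
    unresolved: str = "exclude",
) -> TransitionTable:
    """Count next-in-LOD outcomes over all fixated runs.

    ``unresolved`` selects the handling of observations whose LOD
    (n+1)-genotype is not a superset of the observed genotype:
    ``"exclude"`` (default) removes them from the row denominator,
    ``"none"`` counts them toward the NONE outcome.
    """
    if unresolved not in ("exclude", "none"):
        raise ValueError("unresolved must be 'exclude' or 'none'")
    fixated_runs = [r for r in runs if r.is_fixated]
    if not fixated_runs:
        raise ValueError("no fixated runs")
    G = fixated_runs[0].G
    counts: dict[int, dict] = {}
    excluded: dict[int, int] = {}
    totals: dict[int, int] = {}
    for run in fixated_runs:
        lod_by_n = {n_mutations(g): g for g in run.lod}
        n_fix = n_mutations(run.fixated)
        for i in run.observable:
            n = n_mutations(i)
            totals[i] = totals.get(i, 0) + 1
            row = counts.setdefault(i, {})
            if i == run.fixated or n >= n_fix:
                row[NONE_OUTCOME] = row.get(NONE_OUTCOME, 0) + 1
                continue
            j = lod_by_n[n + 1]
            if (i & ~j) == 0:  # j is a one-mutation superset of i
                row[j] = row.get(j, 0) + 1
            elif unresolved == "none":
                row[NONE_OUTCOME] = row.get(NONE_OUTCOME, 0) + 1
            else:
                excluded[i] = excluded.get(i, 0) + 1
    table = TransitionTable(G=G, rows={})
    for i, row in counts.items():
        denom = sum(row.values())
        if denom == 0:
            continue  # row dropped: every observation was excluded
        table.rows[i] = {o: c / denom for o, c in row.items()}
        table.counts[i] = dict(row)
        table.denominators[i] = denom
        table.other_lineage_fraction[i] = excluded.get(i, 0) / totals[i]
    table.validate()
    return table
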