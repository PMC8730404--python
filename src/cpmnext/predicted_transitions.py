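"""Per-genotype next-step distributions from fitted progression models.

Three flavors convert a fitted model into a row of predicted transition
probabilities over ``row_support(i, G)`` (the one-mutation supersets of
the observed genotype plus the NONE outcome):

* **CE** (competing exponentials): ``p(i -> j) = q_ij / sum_k q_ik`` from
  the model's rate matrix; NONE gets probability 0 unless the genotype
  has no outgoing rate at all.
* **TD** (time-discretized / uniformization): the chain is approximated
  by the discrete transition matrix ``P = I + Q / gamma`` with
  ``gamma = max |q_ii|``; the diagonal entry becomes the NONE
  probability — a lower bound on the probability that the observed
  genotype behaves as a local maximum.  Off the diagonal, TD rows are
  proportional to their CE counterparts.
* **UW** (unweighted): equal mass on every child the fitted structure
  allows (defined for CBN and OT).

Genotypes that are not representable under a fitted structure (e.g.
incompatible with a CBN poset) fall back to a uniform distribution over
all supersets with NONE = 0 and are flagged.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .landscapes import n_mutations, one_mutation_supersets
from .true_transitions import NONE_OUTCOME, TransitionTable, row_support
from .cpm_models import (
    ROOT,
    CBNModel,
    MHNModel,
    OTModel,
    RateMatrix,
    cbn_rate_matrix,
    mhn_rate_matrix,
)

__all__ = [
    "METHOD_LABELS",
    "ce_row",
    "uw_row",
    "time_discretize",
    "td_row",
    "predict_all",
]

#: Method labels in scope: base family x flavor.
METHOD_LABELS = ("MHN", "MHN_td", "CBN", "CBN_td", "CBN_uw", "OT", "OT_uw")

_FLAVORS = {
    "mhn": ("ce", "td"),
    "cbn": ("ce", "td", "uw"),
    "ot": ("ce", "uw"),
}


def _fallback_row(i: int, G: int) -> dict:
    """Uniform over all supersets, NONE = 0 (NONE = 1 for the full genotype)."""
    sups = one_mutation_supersets(i, G)
    if not sups:
        return {NONE_OUTCOME: 1.0}
    return {j: 1.0 / len(sups) for j in sups} | {NONE_OUTCOME: 0.0}


def _rates_to_row(rates: dict[int, float], i: int, G: int) -> dict:
    total = sum(rates.values())
    if total <= 0:
        return {NONE_OUTCOME: 1.0}
    row = {j: r / total for j, r in rates.items()}
    row[NONE_OUTCOME] = 0.0
    return row


def ce_row(rm: RateMatrix, i: int) -> dict:
    """Competing-exponentials row; raises KeyError if ``i`` is not a state."""
    return _rates_to_row(rm.out_rates(i), i, rm.G)


def uw_row(children: Iterable[int], i: int, G: int) -> dict:
    """Equal mass on each allowed child; NONE = 1 when childless."""
    kids = list(children)
    if not kids:
        return {NONE_OUTCOME: 1.0}
    return {j: 1.0 / len(kids) for j in kids} | {NONE_OUTCOME: 0.0}


def time_discretize(rm: RateMatrix) -> np.ndarray:
    """Uniformized transition matrix ``P = I + Q / gamma``.

    ``gamma = max |q_ii|``; rows are stochastic with entries in [0, 1].
    A zero generator yields the identity.
    """
    gamma = float(np.max(np.abs(np.diag(rm.Q))))
    n = rm.Q.shape[0]
    if gamma == 0.0:
        return np.eye(n)
    return np.eye(n) + rm.Q / gamma


def td_row(rm: RateMatrix, i: int, P: np.ndarray | None = None) -> dict:
    """Time-discretized row: NONE = stay-probability ``P_ii``."""
    if P is None:
        P = time_discretize(rm)
    k = rm.index[i]
    row: dict = {NONE_OUTCOME: float(P[k, k])}
    for j in one_mutation_supersets(i, rm.G):
        m = rm.index.get(j)
        if m is not None and P[k, m] > 0:
            row[j] = float(P[k, m])
    return row


def _ot_children(model: OTModel, g: int) -> list[int] | None:
    """Genotypes reachable from ``g`` by adding one tree-addable gene;
    None if ``g`` itself violates the tree."""
    for i in range(model.G):
        if (g >> i) & 1:
            p = model.parent.get(i, ROOT)
            if p != ROOT and not (g >> p) & 1:
                return None
    kids = []
    for i in range(model.G):
        if not (g >> i) & 1:
            p = model.parent.get(i, ROOT)
            if p == ROOT or (g >> p) & 1:
                kids.append(g | (1 << i))
    return kids


def predict_all(model, flavor: str, genotypes: Sequence[int]) -> TransitionTable:
    """One predicted row per requested genotype.

    ``model`` is a fitted :class:`MHNModel`, :class:`CBNModel` or
    :class:`OTModel`; ``flavor`` is ``"ce"``, ``"td"`` or ``"uw"`` (TD only
    for MHN/CBN, UW only for CBN/OT).  Rows for genotypes the model cannot
    represent use the uniform fallback and are flagged
    ``"inaccessible_under_model"``.
    """
    if isinstance(model, MHNModel):
        base = "mhn"
    elif isinstance(model, CBNModel):
        base = "cbn"
    elif isinstance(model, OTModel):
        base = "ot"
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    if flavor not in _FLAVORS[base]:
        raise ValueError(f"flavor {flavor!r} is not defined for {base.upper()}")
    G = model.G
    table = TransitionTable(G=G, rows={})

    rm = None
    P = None
    if base in ("mhn", "cbn") :
        rm = mhn_rate_matrix(model) if base == "mhn" else cbn_rate_matrix(model)
        if flavor == "td":
            P = time_discretize(rm)

    for i in genotypes:
        if n_mutations(i) > G:
            raise ValueError("genotype outside the model's gene set")
        if base == "ot":
            kids = _ot_children(model, i)
            if kids is None:
                table.rows[i] = _fallback_row(i, G)
                table.flags[i] = "inaccessible_under_model"
                continue
            if flavor == "uw":
                table.rows[i] = uw_row(kids, i, G)
            else:  # CE-like: edge weight of the added gene as rate proxy
                rates = {}
                for j in kids:
                    added = (j ^ i).bit_length() - 1
                    rates[j] = model.weights.get(added, 0.0)
                if kids and sum(rates.values()) == 0:
                    table.rows[i] = uw_row(kids, i, G)
                else:
                    table.rows[i] = _rates_to_row(rates, i, G)
            continue
        if i not in rm.index:
            table.rows[i] = _fallback_row(i, G)
            table.flags[i] = "inaccessible_under_model"
            continue
        if flavor == "ce":
            table.rows[i] = ce_row(rm, i)
        elif flavor == "td":
            table.rows[i] = td_row(rm, i, P)
        else:  # uw over the structure's children
            table.rows[i] = uw_row(rm.out_rates(i).keys(), i, G)
    table.validate(atol=1e-9)
    return table
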