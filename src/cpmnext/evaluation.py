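"""Scoring predictions against truth with the Jensen-Shannon distance.

For every observed genotype the truth row and each method's predicted row
are compared on the shared outcome list (supersets plus NONE) using the
Jensen-Shannon distance — the square root of the Jensen-Shannon
divergence with base-2 logarithms, a metric bounded in [0, 1] that is 0
for identical distributions and 1 for distributions with disjoint
support.  The key response variable is the minimal JS over all methods
(the best possible performance), weighted by the truth-row denominators.

The module also computes the genotype- and landscape-level covariates
used to explain performance (number of mutations, fitness rank,
probability of being a local maximum, observability, SSWM index, gamma,
reciprocal sign epistasis, peak count, detection regime, sample size) and
the cross-method agreement analysis used for real data sets, where truth
is unavailable: genotypes whose CE predictions agree (JS <= 0.0677),
whose TD predictions agree, and whose CE and TD predictions differ
(mean JS >= 0.7) are the candidates for trustworthy short-term
prediction.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .landscapes import (
    FitnessLandscape,
    build_fitness_graph,
    count_peaks,
    gamma_statistic,
    genotype_str,
    n_mutations,
    rse_fraction,
)
from .true_transitions import NONE_OUTCOME, TransitionTable, row_support

__all__ = [
    "SIMILAR_JS_THRESHOLD",
    "DIFFERENT_JS_THRESHOLD",
    "js_distance",
    "genotype_covariates",
    "evaluate",
    "method_agreement",
    "stratified_summary",
]

#: Agreement threshold: predictions within one method family are "similar"
#: when their JS distance is at or below this (the 20% best JS in the
#: simulation study).
SIMILAR_JS_THRESHOLD = 0.0677
#: CE and TD predictions are "different" when their mean JS is at or above this.
DIFFERENT_JS_THRESHOLD = 0.7


def js_distance(p, q) -> float:
    """Jensen-Shannon distance between two distributions on a shared support.

    sqrt(0.5 KL(p || m) + 0.5 KL(q || m)) with m = (p + q)/2 and base-2
    logarithms (0 log 0 = 0).  Inputs must be nonnegative and sum to 1
    within 1e-6.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must share a support")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-6 or abs(q.sum() - 1.0) > 1e-6:
        raise ValueError("inputs must be normalized distributions")
    return float(jensenshannon(p, q, base=2))


def _js_rows(truth_row: Mapping, pred_row: Mapping, support: Sequence) -> float:
    p = np.array([truth_row.get(o, 0.0) for o in support])
    q = np.array([pred_row.get(o, 0.0) for o in support])
    return js_distance(p, q)


def genotype_covariates(
    truth: TransitionTable,
    landscape: FitnessLandscape,
    sample=None,
    full_sample=None,
) -> pd.DataFrame:
    """Per-observed-genotype covariates.

    ``fitnessRank`` ranks all 2^G genotypes by descending fitness (global
    maximum = 1); ``propLocalMax`` is 1 when the genotype is a fitness-graph
    peak of this landscape (fractional values only arise when aggregating
    across replicate landscapes); ``observedProp`` is the genotype's row
    frequency in the sample handed to the models and ``diff_obs_prop`` its
    difference from the frequency in the full observation set.
    """
    order = np.argsort(-landscape.fitness, kind="stable")
    rank = np.empty(1 << landscape.G, dtype=int)
    rank[order] = np.arange(1, (1 << landscape.G) + 1)
    peaks = build_fitness_graph(landscape).peaks

    def freq_of(sample_obj):
        if sample_obj is None:
            return None
        ints = sample_obj.genotype_ints()
        vals, cts = np.unique(ints, return_counts=True)
        return dict(zip(vals.tolist(), (cts / cts.sum()).tolist()))

    sample_freq = freq_of(sample)
    full_freq = freq_of(full_sample)
    recs = []
    for g in truth.genotypes():
        obs = sample_freq.get(g, 0.0) if sample_freq is not None else np.nan
        true = full_freq.get(g, 0.0) if full_freq is not None else np.nan
        recs.append(
            {
                "genotype": genotype_str(g, landscape.G),
                "nMut": n_mutations(g),
                "fitnessRank": int(rank[g]),
                "propLocalMax": 1.0 if g in peaks else 0.0,
                "observedProp": obs,
                "diff_obs_prop": obs - true if sample_freq and full_freq else np.nan,
            }
        )
    return pd.DataFrame(recs)


def evaluate(
    truth: TransitionTable,
    predictions: Mapping[str, TransitionTable],
    covariates: pd.DataFrame | None = None,
    context: Mapping | None = None,
) -> pd.DataFrame:
    """Tidy table of JS distances: one row per genotype x method.

    Adds the per-genotype ``min_js`` over all methods (the best possible
    performance) and the truth-row denominator as ``weight``.  A genotype
    missing from a prediction table scores against the uniform fallback
    row and is flagged.
    """
    from .predicted_transitions import _fallback_row

    recs = []
    for g in truth.genotypes():
        support = row_support(g, truth.G)
        tr = truth.rows[g]
        js_by_method = {}
        for label, pred in predictions.items():
            if g in pred.rows:
                pr = pred.rows[g]
                flag = pred.flags.get(g, "")
            else:
                pr = _fallback_row(g, truth.G)
                flag = "missing_prediction"
            js_by_method[label] = (_js_rows(tr, pr, support), flag)
        min_js = min(v[0] for v in js_by_method.values())
        for label, (js, flag) in js_by_method.items():
            rec = {
                "genotype": genotype_str(g, truth.G),
                "method": label,
                "js": js,
                "min_js": min_js,
                "weight": truth.denominators.get(g, np.nan),
                "flag": flag,
            }
            if context:
                rec.update(context)
            recs.append(rec)
    df = pd.DataFrame(recs)
    if covariates is not None:
        df = df.merge(covariates, on="genotype", how="left")
    return df


def landscape_context(
    landscape: FitnessLandscape, runs=None, **extra
) -> dict:
    """Landscape- and dynamics-level covariates shared by all genotypes."""
    from .evolsim import sswm_index

    ctx = {
        "landscape_kind": landscape.kind,
        "gamma": gamma_statistic(landscape),
        "epistRSign": rse_fraction(landscape),
        "numObservedPeaks": count_peaks(landscape),
    }
    if runs is not None:
        ctx["SSWM"] = sswm_index(runs)
    ctx.update(extra)
    return ctx


def method_agreement(
    predictions: Mapping[str, TransitionTable],
    genotypes: Sequence[int] | None = None,
    similar_threshold: float = SIMILAR_JS_THRESHOLD,
    different_threshold: float = DIFFERENT_JS_THRESHOLD,
) -> tuple[pd.DataFrame, dict]:
    """Cross-method agreement on one data set (no truth required).

    Requires predictions for CBN, MHN, CBN_td and MHN_td on the same
    genotypes (the all-mutated genotype should be excluded by the caller).
    Flags per genotype: ``similar_ce`` (JS(CBN, MHN) <= threshold),
    ``similar_td`` (JS(CBN_td, MHN_td) <= threshold) and ``different_ce_td``
    ((JS(CBN, CBN_td) + JS(MHN, MHN_td)) / 2 >= threshold).  Returns the
    per-genotype table and the per-data-set percentages.
    """
    for label in ("CBN", "MHN", "CBN_td", "MHN_td"):
        if label not in predictions:
            raise ValueError(f"missing predictions for {label}")
    G = predictions["CBN"].G
    if genotypes is None:
        genotypes = sorted(
            set.intersection(*(set(predictions[m].rows) for m in predictions))
        )
    recs = []
    for g in genotypes:
        support = row_support(g, G)

        def js(a, b):
            return _js_rows(predictions[a].rows[g], predictions[b].rows[g], support)

        ce = js("CBN", "MHN")
        td = js("CBN_td", "MHN_td")
        ce_td = 0.5 * (js("CBN", "CBN_td") + js("MHN", "MHN_td"))
        recs.append(
            {
                "genotype": genotype_str(g, G),
                "js_ce_pair": ce,
                "js_td_pair": td,
                "js_ce_td_mean": ce_td,
                "similar_ce": ce <= similar_threshold,
                "similar_td": td <= similar_threshold,
                "different_ce_td": ce_td >= different_threshold,
            }
        )
    df = pd.DataFrame(recs)
    n = max(len(df), 1)
    summary = {
        "pct_similar_ce_and_different": 100.0
        * (df["similar_ce"] & df["different_ce_td"]).sum() / n,
        "pct_similar_td_and_different": 100.0
        * (df["similar_td"] & df["different_ce_td"]).sum() / n,
        "pct_both_similar_and_different": 100.0
        * (df["similar_ce"] & df["similar_td"] & df["different_ce_td"]).sum() / n,
        "n_genotypes": len(df),
    }
    return df, summary


def stratified_summary(
    records: pd.DataFrame,
    strata: Sequence[str],
    weight_col: str | None = "weight",
) -> pd.DataFrame:
    """Weighted mean/median min-JS and per-method mean JS within strata.

    Stands in for a full mixed-effects analysis: the tidy ``records`` table
    carries every covariate, so any external statistical tooling can pick
    up from here.  Empty strata are dropped.
    """
    if records.empty:
        raise ValueError("no records to summarize")
    df = records.copy()
    if weight_col is None or weight_col not in df:
        df["_w"] = 1.0
    else:
        df["_w"] = df[weight_col].fillna(1.0)
    rows = []
    for keys, grp in df.groupby(list(strata), dropna=False):
        if grp.empty:
            continue
        keys = keys if isinstance(keys, tuple) else (keys,)
        id_cols = [c for c in grp.columns if c not in ("method", "js", "flag", "_w")]
        per_g = grp.drop_duplicates(subset=id_cols)
        w = per_g["_w"].to_numpy()
        mj = per_g["min_js"].to_numpy()
        order = np.argsort(mj)
        cw = np.cumsum(w[order])
        median = mj[order][np.searchsorted(cw, 0.5 * cw[-1])]
        rec = dict(zip(strata, keys))
        rec["mean_min_js"] = float(np.average(mj, weights=w))
        rec["median_min_js"] = float(median)
        rec["n_genotypes"] = len(per_g)
        for method, mg in grp.groupby("method"):
            rec[f"mean_js_{method}"] = float(
                np.average(mg["js"], weights=mg["_w"])
            )
        rows.append(rec)
    return pd.DataFrame(rows)
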