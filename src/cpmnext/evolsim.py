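"""Stochastic clonal evolution on a fitness landscape.

A tumor is modeled as a multitype birth-death process: each cell of
genotype ``g`` divides at rate ``fitness(g)`` and dies at the
density-dependent rate ``log(1 + N_tot / K)`` (McFarland-style logistic
death), with ``K = N0 / (e - 1)`` so a wild-type population of fitness 1
equilibrates near ``N0``.  At each division every non-mutated locus
mutates independently with probability ``mu`` (no back mutations); because
``mu`` is tiny, double mutations in one division are ignored.

The process is advanced by Poisson tau-leaping over the clone abundances;
leap sizes are small relative to the demographic time scales involved, so
clone establishment and sweep dynamics are faithfully resolved.  A run
terminates when the majority genotype is a (possibly local) fitness peak
at frequency >= ``fixation_threshold``.

Each run records population snapshots at regular intervals, the ancestry
of every clone ever created, the Line of Descent (LOD) of the fixated
genotype, and the set of *observable* genotypes — those that were the
majority of the population in at least one snapshot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .landscapes import (
    WILD_TYPE,
    FitnessLandscape,
    landscape_peaks,
    n_mutations,
    genotype_str,
)

__all__ = [
    "SimConfig",
    "draw_mutation_rates",
    "PopulationSnapshot",
    "EvolutionRun",
    "simulate_run",
    "simulate_runs",
    "line_of_descent",
    "observable_genotypes",
    "sswm_index",
]

#: The study's initial population sizes.
POPULATION_SIZES = (2_000, 50_000, 1_000_000)
#: Fixed per-locus per-division mutation probability.
MU_FIXED = 1e-5
#: Bounds of the log-uniform per-gene mutation rate regime.
MU_LOG_UNIFORM = (0.2e-5, 5e-5)


@dataclass
class SimConfig:
    """Parameters of one evolutionary process."""

    n0: int = 2_000
    mu: float | Sequence[float] = MU_FIXED
    fixation_threshold: float = 0.95
    snapshot_interval: float = 1.0
    tau: float = 0.25
    max_time: float = 50_000.0
    max_population: float = 1e9
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n0 < 1:
            raise ValueError("n0 must be at least 1")
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        if np.any(mu < 0) or np.any(mu >= 1):
            raise ValueError("mutation rates must be in [0, 1)")
        if not 0.5 < self.fixation_threshold <= 1.0:
            raise ValueError("fixation_threshold must be in (0.5, 1]")


def draw_mutation_rates(G: int, regime: str, rng) -> np.ndarray:
    """Per-gene mutation rates under the study's two regimes.

    ``fixed`` gives every gene 1e-5; ``loguniform`` draws each gene's rate
    uniformly on a log scale between 0.2e-5 and 5e-5.
    """
    rng = np.random.default_rng(rng)
    if regime == "fixed":
        return np.full(G, MU_FIXED)
    if regime == "loguniform":
        lo, hi = np.log(MU_LOG_UNIFORM[0]), np.log(MU_LOG_UNIFORM[1])
        return np.exp(rng.uniform(lo, hi, size=G))
    raise ValueError(f"unknown mutation rate regime {regime!r}")


@dataclass
class PopulationSnapshot:
    time: float
    counts: dict[int, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def majority(self) -> int:
        """Most abundant genotype; ties go to fewer mutations, then to the
        lexicographically smallest bitstring."""
        best = max(
            self.counts.items(),
            key=lambda kv: (kv[1], -n_mutations(kv[0]), -kv[0]),
        )
        return best[0]


@dataclass
class EvolutionRun:
    """Result of one simulated evolutionary process."""

    G: int
    history: list[PopulationSnapshot]
    clone_parents: dict[int, int | None]
    fixated: int | None
    seed: int | None = None
    config: SimConfig | None = None
    lod: list[int] = field(default_factory=list)
    observable: dict[int, list[tuple[float, float]]] = field(default_factory=dict)

    @property
    def is_fixated(self) -> bool:
        return self.fixated is not None

    def to_record(self) -> dict:
        """Compact JSON-serializable summary (one line of a run archive)."""
        return {
            "lod": [genotype_str(g, self.G) for g in self.lod],
            "fixated": None if self.fixated is None else genotype_str(self.fixated, self.G),
            "observable": sorted(genotype_str(g, self.G) for g in self.observable),
            "n_snapshots": len(self.history),
            "seed": self.seed,
        }


def simulate_run(landscape: FitnessLandscape, config: SimConfig) -> EvolutionRun:
    """Simulate one process until fixation at a fitness peak (or a cap).

    Runs that hit ``max_time`` or ``max_population`` without fixating, or
    that go extinct, are returned with ``fixated=None`` and are excluded
    from downstream truth tables.
    """
    G = landscape.G
    f = landscape.fitness
    if not landscape.viable(WILD_TYPE):
        raise ValueError("wild type is non-viable")
    peaks = landscape_peaks(landscape)
    mu = np.atleast_1d(np.asarray(config.mu, dtype=float))
    if mu.size == 1:
        mu = np.full(G, float(mu[0]))
    elif mu.size != G:
        raise ValueError("mu must be scalar or have one entry per gene")
    rng = np.random.default_rng(config.seed)

    K = config.n0 / (math.e - 1.0)
    tau = min(config.tau, config.snapshot_interval)
    steps_per_snapshot = max(1, round(config.snapshot_interval / tau))
    tau = config.snapshot_interval / steps_per_snapshot

    # Live clone state as parallel arrays for vectorized leaping.
    genos: list[int] = [WILD_TYPE]
    counts = np.array([config.n0], dtype=np.int64)
    birth = np.array([f[WILD_TYPE]])
    # Per-genotype probability that a division carries a mutation, and the
    # per-locus selection weights.
    free_mask = [np.array([i for i in range(G)])]
    pmut = np.array([1.0 - np.prod(1.0 - mu)])
    clone_parents: dict[int, int | None] = {WILD_TYPE: None}

    history: list[PopulationSnapshot] = []
    fixated: int | None = None
    t = 0.0

    def snapshot_and_check() -> bool:
        nonlocal fixated
        snap = PopulationSnapshot(time=t, counts={g: int(c) for g, c in zip(genos, counts) if c > 0})
        if not snap.counts:
            history.append(snap)
            return True  # extinction
        history.append(snap)
        maj = snap.majority()
        total = snap.total
        if maj in peaks and snap.counts[maj] >= config.fixation_threshold * total:
            fixated = maj
            return True
        return total > config.max_population

    done = snapshot_and_check()
    while not done and t < config.max_time:
        for _ in range(steps_per_snapshot):
            total = int(counts.sum())
            if total == 0:
                break
            death = math.log1p(total / K)
            births = rng.poisson(counts * birth * tau)
            deaths = rng.poisson(counts * death * tau)
            mutants = rng.binomial(births, pmut)
            counts = np.maximum(counts + births - mutants - deaths, 0)
            if mutants.any():
                new: dict[int, int] = {}
                for idx in np.nonzero(mutants)[0]:
                    g = genos[idx]
                    loci = free_mask[idx]
                    w = mu[loci]
                    picks = rng.choice(loci, size=int(mutants[idx]), p=w / w.sum())
                    for locus in picks:
                        child = g | (1 << int(locus))
                        if f[child] <= 0:
                            continue  # non-viable mutants are purged immediately
                        if child not in clone_parents:
                            clone_parents[child] = g
                        new[child] = new.get(child, 0) + 1
                if new:
                    index = {g: i for i, g in enumerate(genos)}
                    for child, k in new.items():
                        if child in index:
                            counts[index[child]] += k
                        else:
                            genos.append(child)
                            counts = np.append(counts, k)
                            birth = np.append(birth, f[child])
                            loci = np.array(
                                [i for i in range(G) if not (child >> i) & 1], dtype=int
                            )
                            free_mask.append(loci)
                            pmut = np.append(
                                pmut, 1.0 - np.prod(1.0 - mu[loci]) if loci.size else 0.0
                            )
            # Drop extinct clones occasionally to keep the arrays short.
            if len(genos) > 8 and (counts == 0).sum() > 4:
                keep = counts > 0
                genos = [g for g, k in zip(genos, keep) if k]
                counts = counts[keep]
                birth = birth[keep]
                free_mask = [m for m, k in zip(free_mask, keep) if k]
                pmut = pmut[keep]
        t += config.snapshot_interval
        done = snapshot_and_check()

    run = EvolutionRun(
        G=G,
        history=history,
        clone_parents=clone_parents,
        fixated=fixated,
        seed=config.seed,
        config=config,
    )
    if fixated is not None:
        run.lod = line_of_descent(run)
    run.observable = observable_genotypes(run)
    return run


def simulate_runs(
    landscape: FitnessLandscape, config: SimConfig, n_runs: int, seed=None
) -> list[EvolutionRun]:
    """Independent replicate runs with per-run seeds derived from ``seed``."""
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_runs):
        cfg = SimConfig(
            n0=config.n0,
            mu=config.mu,
            fixation_threshold=config.fixation_threshold,
            snapshot_interval=config.snapshot_interval,
            tau=config.tau,
            max_time=config.max_time,
            max_population=config.max_population,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        out.append(simulate_run(landscape, cfg))
    return out


def line_of_descent(run: EvolutionRun) -> list[int]:
    """Ancestor chain of the fixated genotype, wild type first.

    Consecutive elements differ by exactly one added mutation; the last
    element is the fixated genotype.
    """
    if run.fixated is None:
        raise ValueError("run did not fixate")
    chain = [run.fixated]
    g = run.fixated
    while g != WILD_TYPE:
        parent = run.clone_parents.get(g)
        if parent is None and g != WILD_TYPE:
            raise RuntimeError("broken ancestry chain")
        if n_mutations(parent) != n_mutations(g) - 1 or (parent & ~g):
            raise RuntimeError("ancestry chain is not a one-mutation chain")
        chain.append(parent)
        g = parent
    chain.reverse()
    return chain


def observable_genotypes(run: EvolutionRun) -> dict[int, list[tuple[float, float]]]:
    """Genotypes that were the population majority in >= 1 snapshot.

    Returns each observable genotype with the list of contiguous time
    intervals over which it was the majority.
    """
    if not run.history:
        raise ValueError("run has no snapshots")
    out: dict[int, list[tuple[float, float]]] = {}
    prev_g: int | None = None
    for snap in run.history:
        if not snap.counts:
            prev_g = None
            continue
        g = snap.majority()
        if g == prev_g:
            start, _ = out[g][-1]
            out[g][-1] = (start, snap.time)
        else:
            out.setdefault(g, []).append((snap.time, snap.time))
        prev_g = g
    return out


def sswm_index(runs: Sequence[EvolutionRun]) -> float:
    """Average frequency of the most frequent genotype.

    The majority frequency is averaged over snapshots within each run and
    then over runs; 1.0 indicates hard selective sweeps (SSWM), lower
    values indicate clonal interference.
    """
    if not runs:
        raise ValueError("need at least one run")
    per_run = []
    for run in runs:
        freqs = []
        for snap in run.history:
            if snap.counts:
                total = snap.total
                freqs.append(max(snap.counts.values()) / total)
        if freqs:
            per_run.append(float(np.mean(freqs)))
    return float(np.mean(per_run))
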