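"""Fitness landscapes over binary genotypes and their characterization.

Genotypes over ``G`` genes are represented as Python integers used as bit
masks: bit ``i`` (``1 << i``) is set when gene ``i`` is mutated.  In string
form gene 0 is the leftmost character, so with ``G = 4`` the integer
``0b0101`` prints as ``"1010"`` (genes 0 and 2 mutated).

Three landscape families are supported, in increasing order of departure
from the assumptions of cancer progression models:

* *representable* — the accessible genotypes and accessible mutational
  paths coincide with those of a restriction DAG; single fitness peak;
* *local maxima* — the accessible genotype set is still DAG-representable
  but the fitness graph has missing paths and at least two peaks;
* *Rough Mount Fuji (RMF)* — an additive slope toward a reference genotype
  plus i.i.d. house-of-cards noise; typically multi-peaked with
  reciprocal sign epistasis, not DAG-representable.

Fitness is on a birth-rate scale: the wild type has fitness 1 and a value
of 0 marks a non-viable genotype.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "WILD_TYPE",
    "genotype_str",
    "genotype_from_str",
    "n_mutations",
    "one_mutation_supersets",
    "hamming",
    "RestrictionDAG",
    "generate_restriction_dag",
    "dag_compatible_genotypes",
    "FitnessLandscape",
    "make_representable_landscape",
    "make_local_maxima_landscape",
    "make_rmf_landscape",
    "FitnessGraph",
    "build_fitness_graph",
    "landscape_peaks",
    "gamma_statistic",
    "rse_fraction",
    "count_peaks",
]

WILD_TYPE = 0

# Fitness values below this floor are treated as non-viable.
VIABILITY_FLOOR = 1e-9


# ---------------------------------------------------------------------------
# Genotype bit-mask helpers
# ---------------------------------------------------------------------------

def genotype_str(g: int, G: int) -> str:
    """Render genotype ``g`` as a fixed-width bitstring, gene 0 leftmost."""
    return "".join("1" if (g >> i) & 1 else "0" for i in range(G))


def genotype_from_str(s: str) -> int:
    g = 0
    for i, ch in enumerate(s):
        if ch == "1":
            g |= 1 << i
        elif ch != "0":
            raise ValueError(f"invalid genotype string {s!r}")
    return g


def n_mutations(g: int) -> int:
    return g.bit_count()


def one_mutation_supersets(g: int, G: int) -> list[int]:
    """Genotypes reachable from ``g`` by one additional mutation, in gene order."""
    return [g | (1 << i) for i in range(G) if not (g >> i) & 1]


def hamming(a: int, b: int) -> int:
    return (a ^ b).bit_count()


# ---------------------------------------------------------------------------
# Restriction DAGs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RestrictionDAG:
    """A DAG of restrictions with AND semantics.

    A gene can only mutate once *all* of its parents are mutated.  Genes are
    integer indices ``0..G-1``; ``parents`` maps a gene to the (possibly
    empty) frozenset of its parents.
    """

    G: int
    parents: Mapping[int, frozenset[int]]

    def __post_init__(self) -> None:
        parents = {i: frozenset(self.parents.get(i, frozenset())) for i in range(self.G)}
        object.__setattr__(self, "parents", parents)
        for gene, ps in parents.items():
            if any(p < 0 or p >= self.G or p == gene for p in ps):
                raise ValueError(f"parent set of gene {gene} references invalid genes")
        if self._has_cycle():
            raise ValueError("restriction graph contains a cycle")

    def _has_cycle(self) -> bool:
        color = [0] * self.G  # 0 white, 1 gray, 2 black

        def visit(u: int) -> bool:
            color[u] = 1
            for p in self.parents[u]:
                if color[p] == 1 or (color[p] == 0 and visit(p)):
                    return True
            color[u] = 2
            return False

        return any(color[u] == 0 and visit(u) for u in range(self.G))

    def to_json(self) -> str:
        return json.dumps(
            {
                "genes": [str(i + 1) for i in range(self.G)],
                "parents": {
                    str(i + 1): sorted(str(p + 1) for p in self.parents[i])
                    for i in range(self.G)
                    if self.parents[i]
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RestrictionDAG":
        d = json.loads(text)
        genes = [int(x) - 1 for x in d["genes"]]
        parents = {
            int(k) - 1: frozenset(int(p) - 1 for p in v)
            for k, v in d.get("parents", {}).items()
        }
        return cls(G=len(genes), parents=parents)


def generate_restriction_dag(G: int, density: float, seed=None) -> RestrictionDAG:
    """Draw a random restriction DAG on ``G`` genes.

    Genes are ranked 0..G-1 and each lower-ranked gene becomes a parent of a
    higher-ranked one independently with probability ``density``; the result
    is acyclic by construction.  ``density=0`` gives an unconstrained
    (empty) DAG.
    """
    if not 2 <= G:
        raise ValueError("need at least two genes")
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    parents: dict[int, frozenset[int]] = {}
    for i in range(G):
        ps = frozenset(j for j in range(i) if rng.random() < density)
        parents[i] = ps
    return RestrictionDAG(G=G, parents=parents)


def dag_compatible_genotypes(dag: RestrictionDAG) -> set[int]:
    """All genotypes in which every mutated gene has all its parents mutated."""
    parent_masks = [
        sum(1 << p for p in dag.parents[i]) for i in range(dag.G)
    ]
    out: set[int] = set()
    for g in range(1 << dag.G):
        ok = True
        for i in range(dag.G):
            if (g >> i) & 1 and (g & parent_masks[i]) != parent_masks[i]:
                ok = False
                break
        if ok:
            out.add(g)
    return out


# ---------------------------------------------------------------------------
# Fitness landscapes
# ---------------------------------------------------------------------------

@dataclass
class FitnessLandscape:
    """Fitness value for every one of the ``2**G`` genotypes.

    ``fitness[g]`` is the birth rate of genotype ``g``; 0 means non-viable.
    ``kind`` tags the generating family and ``params`` records the generator
    arguments (including the seed) for provenance.
    """

    G: int
    fitness: np.ndarray
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fitness = np.asarray(self.fitness, dtype=float)
        if self.fitness.shape != (1 << self.G,):
            raise ValueError("fitness must have one entry per genotype")
        if np.any(self.fitness < 0):
            raise ValueError("fitness values must be nonnegative")
        if not self.viable(WILD_TYPE):
            raise ValueError("wild type must be viable")

    def viable(self, g: int) -> bool:
        return self.fitness[g] > VIABILITY_FLOOR

    @property
    def viable_mask(self) -> np.ndarray:
        return self.fitness > VIABILITY_FLOOR

    def peaks(self) -> set[int]:
        return landscape_peaks(self)

    def to_json(self) -> str:
        return json.dumps(
            {
                "G": self.G,
                "kind": self.kind,
                "params": self.params,
                "fitness": {
                    genotype_str(g, self.G): float(self.fitness[g])
                    for g in range(1 << self.G)
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FitnessLandscape":
        d = json.loads(text)
        G = int(d["G"])
        fitness = np.zeros(1 << G)
        for key, val in d["fitness"].items():
            fitness[genotype_from_str(key)] = val
        return cls(G=G, fitness=fitness, kind=d.get("kind", "custom"),
                   params=d.get("params", {}))


def _multiplicative_baseline(dag: RestrictionDAG, effects: Sequence[float]) -> np.ndarray:
    effects = np.asarray(effects, dtype=float)
    if effects.shape != (dag.G,):
        raise ValueError("need one selection coefficient per gene")
    if np.any(effects <= 0):
        raise ValueError("selection coefficients must be positive")
    fitness = np.zeros(1 << dag.G)
    log1s = np.log1p(effects)
    for g in dag_compatible_genotypes(dag):
        total = sum(log1s[i] for i in range(dag.G) if (g >> i) & 1)
        fitness[g] = math.exp(total)
    return fitness


def make_representable_landscape(
    dag: RestrictionDAG, effects: Sequence[float]
) -> FitnessLandscape:
    """Single-peaked landscape whose accessible paths match the DAG exactly.

    Compatible genotypes get multiplicative fitness ``prod(1 + s_i)`` over
    mutated genes; incompatible genotypes are non-viable.  Because all
    ``s_i > 0``, every DAG-compatible path is fitness-increasing and the
    unique peak is the maximal compatible genotype.
    """
    fitness = _multiplicative_baseline(dag, effects)
    return FitnessLandscape(
        G=dag.G,
        fitness=fitness,
        kind="representable",
        params={"effects": list(map(float, effects)), "dag": json.loads(dag.to_json())},
    )


def make_local_maxima_landscape(
    dag: RestrictionDAG,
    effects: Sequence[float],
    noise_sd: float,
    seed=None,
    max_tries: int = 200,
) -> FitnessLandscape:
    """DAG-representable accessible set, but with at least two fitness peaks.

    The multiplicative baseline is perturbed by genotype-specific lognormal
    noise and rejection-sampled until (a) the set of genotypes accessible
    from the wild type equals the DAG-compatible set, and (b) the fitness
    graph has at least two peaks.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    baseline = _multiplicative_baseline(dag, effects)
    compatible = dag_compatible_genotypes(dag)
    rng = np.random.default_rng(seed)
    for attempt in range(max_tries):
        noise = rng.normal(0.0, noise_sd, size=baseline.shape)
        fitness = baseline * np.exp(noise)
        fitness[baseline == 0] = 0.0
        fitness[WILD_TYPE] = baseline[WILD_TYPE]
        ls = FitnessLandscape(
            G=dag.G,
            fitness=fitness,
            kind="local_maxima",
            params={
                "effects": list(map(float, effects)),
                "noise_sd": float(noise_sd),
                "seed": seed,
                "attempt": attempt,
                "dag": json.loads(dag.to_json()),
            },
        )
        graph = build_fitness_graph(ls)
        if set(graph.nodes) == compatible and len(graph.peaks) >= 2:
            return ls
    raise RuntimeError(
        f"no landscape satisfying the constraints after {max_tries} tries; "
        "noise_sd may be too small (single peak) or too large (inaccessible genotypes)"
    )


def make_rmf_landscape(
    G: int,
    c: float = 0.25,
    reference: int | None = None,
    noise_sd: float = 0.25,
    seed=None,
) -> FitnessLandscape:
    """Rough Mount Fuji landscape: additive slope toward ``reference`` plus noise.

    ``log f(g) = -c * Hamming(g, reference) + xi_g`` with
    ``xi_g ~ Normal(0, noise_sd)``, normalized so the wild type has fitness 1.
    ``c = 0`` with positive noise gives a House-of-Cards landscape.  All
    genotypes are viable.
    """
    if c < 0 or noise_sd < 0:
        raise ValueError("c and noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    if reference is None:
        reference = (1 << G) - 1
    d = np.array([hamming(g, reference) for g in range(1 << G)])
    logf = -c * d + rng.normal(0.0, noise_sd, size=1 << G)
    logf -= logf[WILD_TYPE]  # wild type fitness exactly 1
    fitness = np.exp(logf)
    return FitnessLandscape(
        G=G,
        fitness=fitness,
        kind="rmf",
        params={
            "c": float(c),
            "reference": genotype_str(reference, G),
            "noise_sd": float(noise_sd),
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# Fitness graphs and landscape statistics
# ---------------------------------------------------------------------------

@dataclass
class FitnessGraph:
    """Accessible part of the genotype lattice under fitness-increasing steps.

    Nodes are the genotypes reachable from the wild type through viable,
    strictly fitness-increasing single-mutation additions; ``children`` maps
    each node to its outgoing neighbors and ``peaks`` are the sinks
    (accessible local maxima).  Back mutations and multi-mutation jumps are
    not represented.
    """

    G: int
    nodes: set[int]
    children: dict[int, list[int]]

    @property
    def peaks(self) -> set[int]:
        return {g for g in self.nodes if not self.children[g]}


def build_fitness_graph(landscape: FitnessLandscape) -> FitnessGraph:
    f = landscape.fitness
    G = landscape.G
    if not landscape.viable(WILD_TYPE):
        raise ValueError("wild type is non-viable")
    nodes: set[int] = set()
    children: dict[int, list[int]] = {}
    stack = [WILD_TYPE]
    nodes.add(WILD_TYPE)
    while stack:
        g = stack.pop()
        kids = [
            h
            for h in one_mutation_supersets(g, G)
            if f[h] > VIABILITY_FLOOR and f[h] > f[g]
        ]
        children[g] = kids
        for h in kids:
            if h not in nodes:
                nodes.add(h)
                stack.append(h)
    return FitnessGraph(G=G, nodes=nodes, children=children)


def landscape_peaks(landscape: FitnessLandscape) -> set[int]:
    """Viable genotypes with no fitter viable one-mutation superset.

    With no back mutations the only moves are mutation additions, so these
    are exactly the genotypes at which fixation can occur.  This set
    includes the fitness-graph peaks plus any maxima not accessible from
    the wild type.
    """
    f = landscape.fitness
    G = landscape.G
    out = set()
    for g in range(1 << G):
        if f[g] <= VIABILITY_FLOOR:
            continue
        if all(
            not (f[h] > VIABILITY_FLOOR and f[h] > f[g])
            for h in one_mutation_supersets(g, G)
        ):
            out.add(g)
    return out


def count_peaks(landscape: FitnessLandscape) -> int:
    """Number of accessible fitness maxima (sinks of the fitness graph)."""
    return len(build_fitness_graph(landscape).peaks)


def gamma_statistic(landscape: FitnessLandscape) -> float:
    """Correlation of fitness effects of the same mutation in single-mutant neighbors.

    Over all ordered locus pairs (i, j), i != j, and all backgrounds g with
    both loci wild type and g, g+e_i, g+e_j, g+e_i+e_j viable, collect
    (f(g+e_j) - f(g), f(g+e_i+e_j) - f(g+e_i)) and return the Pearson
    correlation.  1 on additive landscapes; near 0 when epistasis dominates.
    Returns NaN when undefined (no pairs or zero variance).
    """
    f = landscape.fitness
    G = landscape.G
    if G < 2:
        raise ValueError("need at least two loci")
    viable = landscape.viable_mask
    xs: list[float] = []
    ys: list[float] = []
    for i in range(G):
        for j in range(G):
            if i == j:
                continue
            bi, bj = 1 << i, 1 << j
            for g in range(1 << G):
                if g & (bi | bj):
                    continue
                quad = (g, g | bi, g | bj, g | bi | bj)
                if all(viable[q] for q in quad):
                    xs.append(f[g | bj] - f[g])
                    ys.append(f[g | bi | bj] - f[g | bi])
    if len(xs) < 2:
        return float("nan")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def rse_fraction(landscape: FitnessLandscape, per_square: bool = False) -> float:
    """Fraction of locus pairs exhibiting reciprocal sign epistasis.

    A two-locus square (g, g+e_i, g+e_j, g+e_i+e_j) with all four genotypes
    viable shows reciprocal sign epistasis when the fitness effect of each
    mutation changes sign between the two backgrounds it can be placed on.
    By default a pair {i, j} counts if *any* of its squares is reciprocal-
    sign-epistatic and the fraction is over pairs with at least one viable
    square; with ``per_square=True`` the fraction is over all viable
    squares instead.  Returns NaN when there are no viable squares.
    """
    f = landscape.fitness
    G = landscape.G
    if G < 2:
        raise ValueError("need at least two loci")
    viable = landscape.viable_mask
    pair_total = 0
    pair_rse = 0
    sq_total = 0
    sq_rse = 0
    for i in range(G):
        for j in range(i + 1, G):
            bi, bj = 1 << i, 1 << j
            seen = False
            hit = False
            for g in range(1 << G):
                if g & (bi | bj):
                    continue
                quad = (g, g | bi, g | bj, g | bi | bj)
                if not all(viable[q] for q in quad):
                    continue
                seen = True
                sq_total += 1
                di_wt = np.sign(f[g | bi] - f[g])
                di_alt = np.sign(f[g | bi | bj] - f[g | bj])
                dj_wt = np.sign(f[g | bj] - f[g])
                dj_alt = np.sign(f[g | bi | bj] - f[g | bi])
                if di_wt != di_alt and dj_wt != dj_alt:
                    sq_rse += 1
                    hit = True
            if seen:
                pair_total += 1
                if hit:
                    pair_rse += 1
    if per_square:
        return sq_rse / sq_total if sq_total else float("nan")
    return pair_rse / pair_total if pair_total else float("nan")
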