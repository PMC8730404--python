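import numpy as np
import pytest

from cpmnext import RestrictionDAG, make_representable_landscape
from cpmnext.evolsim import EvolutionRun, PopulationSnapshot


@pytest.fixture
def fig_dag():
    """Four genes; the last one requires the 2nd and 3rd (genes 1 and 2)."""
    return RestrictionDAG(G=4, parents={3: frozenset({1, 2})})


@pytest.fixture
def chain_dag():
    return RestrictionDAG(G=3, parents={1: frozenset({0}), 2: frozenset({1})})


@pytest.fixture
def rep_landscape(fig_dag):
    return make_representable_landscape(fig_dag, [0.2, 0.15, 0.1, 0.25])


def make_run(G, lod, observable, fixated=None, history=None):
    """Hand-built run carrying just what truth tables and sampling need."""
    run = EvolutionRun(
        G=G,
        history=history or [],
        clone_parents={},
        fixated=(lod[-1] if lod else None) if fixated is None else fixated,
    )
    run.lod = list(lod)
    run.observable = {g: [] for g in observable}
    return run


def snapshots(counts_seq, t0=0.0, dt=1.0):
    return [
        PopulationSnapshot(time=t0 + k * dt, counts=dict(c))
        for k, c in enumerate(counts_seq)
    ]
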