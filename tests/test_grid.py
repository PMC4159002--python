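"""Spatial Monte Carlo simulator: invariants, mutation, interventions."""

import numpy as np
import pytest

from rnaqs.grid import (AbundanceObserver, AncestryObserver,
                        HDHistogramObserver, SimParams, World, evolve_mu,
                        init_competition, lineage_counts, mutate_copy)
from rnaqs.phenotype import FuncClass
from rnaqs.seq import hamming, reverse_complement
from tests.conftest import FALLBACK_UNIT


def small_params(**kw):
    defaults = dict(width=24, height=24, mu=0.0)
    defaults.update(kw)
    return SimParams(**defaults)


# -- mutate_copy / evolve_mu -------------------------------------------------

def test_mutate_copy_faithful_at_zero_mu():
    rng = np.random.default_rng(0)
    seq, n = mutate_copy(FALLBACK_UNIT, 0.0, rng)
    assert seq == reverse_complement(FALLBACK_UNIT)
    assert n == 0


def test_mutate_copy_forced_at_mu_one():
    rng = np.random.default_rng(0)
    seq, n = mutate_copy(FALLBACK_UNIT, 1.0, rng)
    rc = reverse_complement(FALLBACK_UNIT)
    assert n == len(seq)
    assert all(a != b for a, b in zip(seq, rc))


def test_mutate_copy_substitution_rate():
    rng = np.random.default_rng(1)
    total = sum(mutate_copy("ACGU" * 25, 0.1, rng)[1] for _ in range(200))
    # Binomial(200*100, 0.1): mean 2000, sd ~42
    assert 1800 < total < 2200


def test_evolve_mu_modes():
    rng = np.random.default_rng(2)
    p_pos = small_params(evolve_mu=True, mu_step=5e-4, mu_mode="positive")
    draws = [evolve_mu(0.001, rng, p_pos) for _ in range(200)]
    assert all(0.001 <= m <= 0.001 + 5e-4 for m in draws)
    p_unb = small_params(evolve_mu=True, mu_step=5e-4, mu_mode="unbiased")
    draws = [evolve_mu(0.001, rng, p_unb) for _ in range(200)]
    assert any(m < 0.001 for m in draws) and any(m > 0.001 for m in draws)
    p_zero = small_params(evolve_mu=True, mu_step=0.0)
    assert evolve_mu(0.42, rng, p_zero) == pytest.approx(0.42)


# -- world dynamics ----------------------------------------------------------

def test_occupancy_and_adjacency_invariants(fallback_engine):
    world = World(small_params(mu=0.02), fallback_engine, seed=11)
    world.populate([FALLBACK_UNIT], density=0.4)
    for _ in range(25):
        world.mc_step()
        world.check_invariants()


def test_population_bookkeeping(fallback_engine):
    """Population changes only through births (+1) and deaths (-1)."""
    world = World(small_params(), fallback_engine, seed=3)
    world.populate([FALLBACK_UNIT], density=0.4)
    seeded = len(world.grid)
    world.run(30)
    births = len(world.birth_log) - seeded
    assert len(world.grid) == seeded + births - world.death_count


def test_seeded_determinism(fallback_engine):
    runs = []
    for _ in range(2):
        world = World(small_params(mu=0.05), fallback_engine, seed=123)
        world.populate([FALLBACK_UNIT], density=0.3)
        world.run(15)
        runs.append((world.snapshot(),
                     sorted((m.id, m.pos, m.sequence) for m in world.molecules())))
    assert runs[0] == runs[1]


def test_faithful_replication_closure(fallback_engine):
    """At mu=0 every molecule is the founder strand or its complement, and
    with decay off the population never shrinks."""
    world = World(small_params(decay_rate=0.0), fallback_engine, seed=5)
    # seed both strands: the C-rich 5' tail binds the complement's G-rich
    # 3' tail, so complexes form between opposite strands
    world.populate([FALLBACK_UNIT, reverse_complement(FALLBACK_UNIT)],
                   density=0.2)
    pops = [len(world.grid)]
    for _ in range(20):
        world.mc_step()
        pops.append(len(world.grid))
    assert all(b >= a for a, b in zip(pops, pops[1:]))
    assert pops[-1] > pops[0]     # replication actually happened
    allowed = {FALLBACK_UNIT, reverse_complement(FALLBACK_UNIT)}
    assert {m.sequence for m in world.molecules()} <= allowed


def test_no_catalysis_means_decline(fallback_engine):
    """Without catalytic molecules the population is non-increasing and
    extinction is absorbing."""
    world = World(small_params(decay_rate=0.1), fallback_engine, seed=7)
    world.populate(["A" * 50], density=0.3)   # parasite: no replicase
    pops = [len(world.grid)]
    for _ in range(80):
        world.mc_step()
        pops.append(len(world.grid))
    assert all(b <= a for a, b in zip(pops, pops[1:]))
    assert pops[-1] == 0


def test_single_molecule_never_replicates(fallback_engine):
    world = World(small_params(decay_rate=0.0), fallback_engine, seed=9)
    world.add_molecule(FALLBACK_UNIT, (5, 5))
    world.run(30)
    assert len(world.grid) == 1


def test_evolvable_mu_increases(fallback_engine):
    world = World(small_params(mu=0.02, evolve_mu=True, mu_step=5e-3),
                  fallback_engine, seed=21)
    world.populate([FALLBACK_UNIT, reverse_complement(FALLBACK_UNIT)],
                   density=0.4)
    world.run(40)
    mus = [m.mu for m in world.molecules()]
    assert mus and max(mus) > 0.02   # some lineage picked up a mu kick


# -- interventions -----------------------------------------------------------

def test_remove_class_intervention(fallback_engine):
    world = World(small_params(mu=0.05), fallback_engine, seed=13)
    world.populate([FALLBACK_UNIT], density=0.4)
    world.add_intervention("remove_class", FuncClass.STALLER)
    for _ in range(20):
        world.mc_step()
        counts = world.class_counts()
        assert counts.get(FuncClass.STALLER, 0) == 0


def test_class_to_junk_intervention(fallback_engine):
    world = World(small_params(mu=0.05), fallback_engine, seed=14)
    world.populate([FALLBACK_UNIT], density=0.4)
    world.add_intervention("class_to_junk", FuncClass.STALLER)
    for _ in range(20):
        world.mc_step()
        for m in world.molecules():
            if m.inert:
                assert m.partner is None   # junk-ified molecules never bind


def test_unknown_intervention_rejected(fallback_engine):
    world = World(small_params(), fallback_engine)
    with pytest.raises(ValueError):
        world.add_intervention("nuke", FuncClass.HELPER)


# -- competition and observers ----------------------------------------------

def test_init_competition_halves(fallback_engine):
    world = World(small_params(), fallback_engine, seed=17)
    other = "A" * 50
    init_competition(world, [FALLBACK_UNIT], [other], density=0.5)
    w = world.params.width
    for m in world.molecules():
        if m.lineage == 0:
            assert m.pos[0] < w // 2
        else:
            assert m.pos[0] >= w // 2
    counts = lineage_counts(world)
    assert counts[0] > 0 and counts[1] > 0


def test_competition_winner_has_descendants(fallback_engine):
    """A replicating lineage outlives an inert one."""
    world = World(small_params(decay_rate=0.05), fallback_engine, seed=19)
    both = [FALLBACK_UNIT, reverse_complement(FALLBACK_UNIT)]
    init_competition(world, both, ["A" * 50], density=0.4)
    world.run(60)
    counts = lineage_counts(world)
    assert counts.get(0, 0) > counts.get(1, 0)


def test_observers(fallback_engine):
    world = World(small_params(mu=0.02), fallback_engine, seed=23)
    world.populate([FALLBACK_UNIT], density=0.3)
    ab, hd, anc = (AbundanceObserver(),
                   HDHistogramObserver(FALLBACK_UNIT), AncestryObserver())
    world.add_observer(ab, interval=5)
    world.add_observer(hd, interval=5)
    world.add_observer(anc, interval=5)
    world.run(15)
    frame = ab.frame()
    assert list(frame["step"]) == [5, 10, 15]
    assert (frame["total"] >= 0).all()
    # every founder (unit or its complement) lands in HD bin 0
    step0_hist = hd.records[0][1]
    assert 0 in step0_hist
    assert set(anc.frame()["id"]) <= {rec[0] for rec in world.birth_log}


def test_hd_histogram_minimum_rule(fallback_engine):
    world = World(small_params(), fallback_engine, seed=25)
    world.add_molecule(reverse_complement(FALLBACK_UNIT), (1, 1))
    obs = HDHistogramObserver(FALLBACK_UNIT)
    obs.observe(world)
    assert obs.records[0][1] == {0: 1}


def test_snapshot_codes(fallback_engine):
    world = World(small_params(), fallback_engine, seed=27)
    world.add_molecule(FALLBACK_UNIT, (0, 0))
    world.add_molecule("A" * 50, (1, 0))
    snap = world.snapshot()
    assert snap[0][0] == "U" and snap[0][1] == "P"
    assert set("".join(snap)) <= set("UPHSJY.")
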