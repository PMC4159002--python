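"""Mutational-neighborhood searches, neutrality, consensus, networks."""

import itertools

import numpy as np
import pytest

from rnaqs.folding import StrandProfile
from rnaqs.phenotype import FuncClass, Genotype, classify, genotype_of
from rnaqs.seq import (canonical_strand, genotype_hamming, hamming,
                       reverse_complement)
from rnaqs.spectrum import (build_network, consensus_and_master,
                            expand_core_neutral, expand_pseudo_neutral,
                            hd1_mutants, hd1_spectrum, replication_rate_proxy,
                            sample_at_hd, screen_random, tails_only_spectrum)
from tests.conftest import FALLBACK_UNIT

# shorter designed unit (same construction as FALLBACK_UNIT) keeps the
# breadth-first expansion tests cheap: 99 single-substitution mutants
SHORT_UNIT = "CCCCCAAUAUCCCAUACUUACCCUAAUUCCCCC"


class OpenChainEngine:
    """Engine double folding everything into an open chain."""

    name = "open-chain"

    def fold(self, seq):
        return "." * len(seq)


def test_hd1_mutant_enumeration():
    muts = list(hd1_mutants(FALLBACK_UNIT))
    assert len(muts) == 150                       # 3 * nu for nu = 50
    assert len(set(muts)) == 150
    assert all(hamming(m, FALLBACK_UNIT) == 1 for m in muts)


def test_hd1_spectrum_fractions(fallback_engine):
    g = genotype_of(FALLBACK_UNIT, fallback_engine)
    sp = hd1_spectrum(g, fallback_engine)
    assert sp.n_mutants == 150
    assert sum(sp.fractions.values()) == pytest.approx(1.0)
    assert 0.0 <= sp.lambda_neutral <= 1.0
    # independent recount of the neutral fraction
    direct = sum(genotype_of(m, fallback_engine).func_class
                 is FuncClass.UNIT_OF_REPLICATION
                 for m in hd1_mutants(FALLBACK_UNIT)) / 150
    assert sp.lambda_neutral == pytest.approx(direct)


def test_hd1_spectrum_forced_classification():
    """Short open chains have tails too weak to bind: everything is junk."""
    eng = OpenChainEngine()
    g = genotype_of("ACGU", eng)
    sp = hd1_spectrum(g, eng)
    assert sp.lambda_neutral == 0.0
    assert sp.fractions[FuncClass.JUNK] == pytest.approx(1.0)


def test_tails_only_spectrum(fallback_engine):
    g = genotype_of(SHORT_UNIT, fallback_engine)
    k = len(g.plus.tail5) + len(g.plus.tail3)
    assert k == 10
    sp = tails_only_spectrum(g, fallback_engine)
    assert sp.n_mutants == 3 * k
    assert sum(sp.fractions.values()) == pytest.approx(1.0)


def test_tails_only_requires_catalytic_strand():
    eng = OpenChainEngine()
    with pytest.raises(ValueError):
        tails_only_spectrum(genotype_of("ACGUACGU", eng), eng)


# -- replication-rate proxy ---------------------------------------------------

def _geno(p5, pcat, p3, tails=("CCCCC", "GGGGG")):
    t5, t3 = tails
    plus = StrandProfile(sequence="x", dotbracket="", coarse="",
                         tail5=t5 if p5 else "", tail3=t3,
                         catalytic=pcat, has5=p5, has3=True)
    minus = StrandProfile(sequence="y", dotbracket="", coarse="",
                          tail5="", tail3=t3, catalytic=False,
                          has5=False, has3=True)
    bits = plus.bits + minus.bits
    return Genotype(plus=plus, minus=minus, bits=bits,
                    func_class=classify(bits))


def test_proxy_zero_without_replicase():
    g = _geno(False, False, True)
    assert replication_rate_proxy(g) == 0.0


def test_proxy_perfect_binding_approaches_one():
    g = _geno(True, True, True, tails=("C" * 30, "G" * 30))
    assert replication_rate_proxy(g) > 0.98


def test_proxy_strand_swap_invariant(fallback_engine):
    g = genotype_of(FALLBACK_UNIT, fallback_engine)
    g_rc = genotype_of(reverse_complement(FALLBACK_UNIT), fallback_engine)
    assert replication_rate_proxy(g) == pytest.approx(replication_rate_proxy(g_rc))


# -- random screening ---------------------------------------------------------

def test_screen_random_empty():
    res = screen_random(0, 50, 0, OpenChainEngine())
    assert res.units == [] and res.n_screened == 0


def test_screen_random_counts(fallback_engine):
    res = screen_random(300, 20, 7, fallback_engine, compute_neutrality=False)
    assert sum(res.class_counts.values()) == 300
    for g in res.units:
        assert g.func_class is FuncClass.UNIT_OF_REPLICATION


# -- expansions ---------------------------------------------------------------

def test_expansions_and_oracle(fallback_engine):
    master = genotype_of(SHORT_UNIT, fallback_engine)
    core = expand_core_neutral(master, 2, fallback_engine, cap_found=12, seed=1)
    pseudo = expand_pseudo_neutral(master, 2, fallback_engine, cap_found=12,
                                   seed=1)
    # HD=0 layer is the master itself
    assert core.table.iloc[0]["n_units"] == 1
    # pseudo-neutral finds a superset of core-neutral at each distance
    for hd in (1, 2):
        c = core.table[core.table.hd == hd]
        p = pseudo.table[pseudo.table.hd == hd]
        if len(c) and len(p):
            assert p.iloc[0]["n_found"] >= c.iloc[0]["n_found"]
    # oracle: the HD=1 pseudo layer equals the distinct unit genotypes among
    # the single-substitution mutants
    units = {canonical_strand(m) for m in hd1_mutants(SHORT_UNIT)
             if genotype_of(m, fallback_engine).func_class
             is FuncClass.UNIT_OF_REPLICATION}
    units -= {canonical_strand(SHORT_UNIT)}
    assert pseudo.table[pseudo.table.hd == 1].iloc[0]["n_found"] == len(units)
    # fraction tables normalize where units were found
    row = pseudo.table[pseudo.table.hd == 1].iloc[0]
    total = sum(row[f"{fc.value}_mean"] for fc in FuncClass)
    assert total == pytest.approx(1.0)


def test_expansion_rejects_non_unit():
    eng = OpenChainEngine()
    with pytest.raises(ValueError):
        expand_core_neutral(genotype_of("ACGU", eng), 1, eng)


def test_sample_at_hd_matches_exhaustive(fallback_engine):
    master = genotype_of(SHORT_UNIT, fallback_engine)
    res = sample_at_hd(master, [1], fallback_engine, cap_found=10_000,
                       cap_tries=2000, seed=3)
    exhaustive = {canonical_strand(m) for m in hd1_mutants(SHORT_UNIT)
                  if genotype_of(m, fallback_engine).func_class
                  is FuncClass.UNIT_OF_REPLICATION}
    assert res.table.iloc[0]["n_found"] == len(exhaustive)


def test_sample_at_hd_stopping_rule():
    eng = OpenChainEngine()
    master_seq = "ACGU" * 5
    g = genotype_of(master_seq, eng)
    res = sample_at_hd(g, [2], eng, cap_found=10, cap_tries=50, seed=5)
    assert res.table.iloc[0]["n_units"] == 0      # nothing viable, stops


# -- consensus / master -------------------------------------------------------

def test_consensus_homogeneous():
    cons, master = consensus_and_master(["AAAA"] * 5)
    assert cons == master == "AAAA"


def test_consensus_plurality():
    cons, master = consensus_and_master(["AAAA"] * 3 + ["AAAU"])
    assert cons == "AAAA" and master == "AAAA"


def test_consensus_column_mode_oracle():
    pop = ["ACGA", "ACGA", "ACUA", "AGGA", "ACGA"]
    cons, master = consensus_and_master(pop)
    expected = "".join(max("ACGU", key=lambda b: sum(s[i] == b for s in pop))
                       for i in range(4))
    assert cons == expected
    assert master == "ACGA"
    with pytest.raises(ValueError):
        consensus_and_master([])


def test_consensus_orients_complements():
    """Strands stored in opposite orientation are folded onto one
    consensus."""
    seq = "AACGGAUC"
    pop = [seq, seq, reverse_complement(seq), seq]
    cons, master = consensus_and_master(pop)
    assert master == seq
    assert cons == seq


# -- network ------------------------------------------------------------------

def test_network_edges_match_pairwise_hd(fallback_engine):
    master = FALLBACK_UNIT
    muts = [m for m in itertools.islice(hd1_mutants(master), 0, 12)]
    units = [genotype_of(s, fallback_engine) for s in [master] + muts]
    graph = build_network(units, master)
    keys = list(graph.nodes)
    expected = {(a, b) for i, a in enumerate(keys) for b in keys[i + 1:]
                if genotype_hamming(a, b) == 1}
    got = {tuple(sorted(e)) for e in graph.edges}
    assert got == {tuple(sorted(e)) for e in expected}
    assert graph.nodes[canonical_strand(master)]["hd_to_master"] == 0


def test_network_single_node(fallback_engine):
    g = genotype_of(FALLBACK_UNIT, fallback_engine)
    graph = build_network([g], FALLBACK_UNIT)
    assert graph.number_of_nodes() == 1 and graph.number_of_edges() == 0
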