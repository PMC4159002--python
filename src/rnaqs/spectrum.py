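"""Mutational-neighborhood analysis of replicator genotypes.

Centered on a reference genotype (typically the master sequence of an
evolved quasispecies), these tools enumerate or sample mutants at given
Hamming distances, classify them into functional classes, and summarize
the result as per-distance class-fraction tables.  The headline statistic
is the neutrality ``lambda``: the fraction of the 3*nu single-substitution
mutants of a genotype that remain units of replication.

Three complementary searches probe larger distances: a breadth-first
expansion keeping only units with replication rate at least that of the
reference ("core neutral"), the same expansion keeping any unit of
replication ("pseudo neutral"), and direct random sampling of mutants at
each exact Hamming distance with explicit stopping rules.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energy import DEFAULT_ENERGY, EnergyParams, binding_probability, gmin
from .folding import FoldEngine
from .phenotype import FuncClass, Genotype, genotype_of
from .seq import (canonical_strand, genotype_hamming, hamming,
                  random_sequence, reverse_complement)

_BASES = "ACGU"


def hd1_mutants(seq: str):
    """All 3*len(seq) single-substitution mutants, in position order."""
    for i, b in enumerate(seq):
        for alt in _BASES:
            if alt != b:
                yield seq[:i] + alt + seq[i + 1:]


@dataclass
class Hd1Spectrum:
    """Class fractions over the single-substitution neighborhood."""

    reference: str
    n_mutants: int
    fractions: dict               # FuncClass -> fraction

    @property
    def lambda_neutral(self) -> float:
        return self.fractions[FuncClass.UNIT_OF_REPLICATION]

    def lam(self, fc: FuncClass) -> float:
        return self.fractions[fc]


@dataclass
class SpectrumResult:
    """Per-Hamming-distance summary of a neighborhood search.

    ``table`` has one row per HD with the number of retained units, the
    mean and std over those units of their own HD=1 class fractions, plus
    bookkeeping on sampling caps.
    """

    reference: str
    table: pd.DataFrame
    caps_hit: dict = field(default_factory=dict)


def _fractions(genotypes) -> dict:
    counts = Counter(g.func_class for g in genotypes)
    n = len(genotypes)
    return {fc: counts.get(fc, 0) / n for fc in FuncClass}


def hd1_spectrum(genotype: Genotype, engine: FoldEngine,
                 params: EnergyParams = DEFAULT_ENERGY) -> Hd1Spectrum:
    """Classify every single-substitution mutant of the plus strand."""
    muts = [genotype_of(m, engine, params)
            for m in hd1_mutants(genotype.plus.sequence)]
    return Hd1Spectrum(reference=genotype.plus.sequence,
                       n_mutants=len(muts), fractions=_fractions(muts))


def tails_only_spectrum(genotype: Genotype, engine: FoldEngine,
                        params: EnergyParams = DEFAULT_ENERGY) -> Hd1Spectrum:
    """Single substitutions restricted to the dangling ends of the
    catalytic strand (a modularity probe: if function were confined to the
    paired core, tail mutations would be mostly neutral)."""
    if genotype.plus.catalytic:
        strand = genotype.plus
    elif genotype.minus.catalytic:
        strand = genotype.minus
    else:
        raise ValueError("genotype has no catalytic strand")
    seq = strand.sequence
    n5, n3 = len(strand.tail5), len(strand.tail3)
    positions = list(range(n5)) + list(range(len(seq) - n3, len(seq)))
    if not positions:
        raise ValueError("catalytic strand has no dangling ends to mutate")
    muts = []
    for i in positions:
        for alt in _BASES:
            if alt != seq[i]:
                muts.append(genotype_of(seq[:i] + alt + seq[i + 1:], engine, params))
    return Hd1Spectrum(reference=seq, n_mutants=len(muts),
                       fractions=_fractions(muts))


def replication_rate_proxy(genotype: Genotype,
                           params: EnergyParams = DEFAULT_ENERGY) -> float:
    """Scalar replication rate of a genotype in [0, 1].

    For a replicase-like strand c (catalytic, 5' tail present) and the
    opposite strand t, the proxy is the mean of the binding probabilities
    of c presenting its 5' tail against another copy of itself and against
    the complement: 1/2 [P(c5 . c3) + P(c5 . t3)].  Maximal (-> 1) when
    both bindings are certain; 0 when no strand can act as replicase.  If
    both strands are replicase-like, the better one counts.
    """
    best = 0.0
    for c, t in ((genotype.plus, genotype.minus), (genotype.minus, genotype.plus)):
        if c.catalytic and c.has5:
            p_self = binding_probability(gmin(c.tail5, c.tail3, params))
            p_comp = binding_probability(gmin(c.tail5, t.tail3, params))
            best = max(best, 0.5 * (p_self + p_comp))
    return best


@dataclass
class ScreenResult:
    """Outcome of screening uniform random sequences for function."""

    n_screened: int
    class_counts: dict            # FuncClass -> count
    units: list                   # Genotype objects found
    both_catalytic_fraction: float
    mean_unit_neutrality: float
    unit_neutralities: list


def screen_random(n: int, length: int, seed, engine: FoldEngine,
                  params: EnergyParams = DEFAULT_ENERGY,
                  compute_neutrality: bool = True) -> ScreenResult:
    """Draw *n* uniform random sequences, classify them and keep the units
    of replication, with summary statistics over those units."""
    rng = np.random.default_rng(seed)
    counts = Counter()
    units = []
    for _ in range(n):
        g = genotype_of(random_sequence(length, rng), engine, params)
        counts[g.func_class] += 1
        if g.func_class is FuncClass.UNIT_OF_REPLICATION:
            units.append(g)
    both_cat = (sum(g.plus.catalytic and g.minus.catalytic for g in units) / len(units)
                if units else float("nan"))
    lams = []
    if compute_neutrality:
        lams = [hd1_spectrum(g, engine, params).lambda_neutral for g in units]
    mean_lam = float(np.mean(lams)) if lams else float("nan")
    return ScreenResult(n_screened=n,
                        class_counts={fc: counts.get(fc, 0) for fc in FuncClass},
                        units=units, both_catalytic_fraction=both_cat,
                        mean_unit_neutrality=mean_lam, unit_neutralities=lams)


# -- higher-Hamming-distance searches ---------------------------------------


def _layer_stats(hd, genotypes, engine, params, caps_hit, cap, n_found=None):
    """Mean/std over a retained layer of each genotype's HD=1 fractions."""
    row = {"hd": hd, "n_units": len(genotypes),
           "n_found": len(genotypes) if n_found is None else n_found}
    if len(genotypes) > cap:
        caps_hit[hd] = len(genotypes)
    per_class = {fc: [] for fc in FuncClass}
    for g in genotypes:
        fr = hd1_spectrum(g, engine, params).fractions
        for fc in FuncClass:
            per_class[fc].append(fr[fc])
    for fc in FuncClass:
        vals = per_class[fc]
        row[f"{fc.value}_mean"] = float(np.mean(vals)) if vals else float("nan")
        row[f"{fc.value}_std"] = float(np.std(vals)) if vals else float("nan")
    return row


def _expand(master: Genotype, max_hd: int, cap_found: int, engine, params,
            seed, rate_filter: bool) -> SpectrumResult:
    if master.func_class is not FuncClass.UNIT_OF_REPLICATION:
        raise ValueError("expansion must start from a unit of replication")
    rng = np.random.default_rng(seed)
    ref_rate = replication_rate_proxy(master, params)
    seen = {canonical_strand(master.plus.sequence)}
    layer = [master]
    caps_hit: dict = {}
    rows = [_layer_stats(0, layer, engine, params, caps_hit, cap_found)]
    for hd in range(1, max_hd + 1):
        found = []
        for g in layer:
            for m in hd1_mutants(g.plus.sequence):
                key = canonical_strand(m)
                if key in seen:
                    continue
                seen.add(key)
                gm = genotype_of(m, engine, params)
                if gm.func_class is not FuncClass.UNIT_OF_REPLICATION:
                    continue
                if rate_filter and replication_rate_proxy(gm, params) < ref_rate:
                    continue
                found.append(gm)
        n_found = len(found)
        if len(found) > cap_found:
            caps_hit[hd] = len(found)
            idx = rng.permutation(len(found))[:cap_found]
            found = [found[i] for i in idx]
        rows.append(_layer_stats(hd, found, engine, params, caps_hit, cap_found,
                                 n_found=n_found))
        layer = found
        if not layer:
            break
    return SpectrumResult(reference=master.plus.sequence,
                          table=pd.DataFrame(rows), caps_hit=caps_hit)


def expand_core_neutral(master: Genotype, max_hd: int, engine: FoldEngine,
                        params: EnergyParams = DEFAULT_ENERGY,
                        cap_found: int = 10_000, seed=0) -> SpectrumResult:
    """Breadth-first expansion retaining units of replication whose
    replication rate is at least that of the master ("core neutral")."""
    return _expand(master, max_hd, cap_found, engine, params, seed,
                   rate_filter=True)


def expand_pseudo_neutral(master: Genotype, max_hd: int, engine: FoldEngine,
                          params: EnergyParams = DEFAULT_ENERGY,
                          cap_found: int = 10_000, seed=0) -> SpectrumResult:
    """Breadth-first expansion retaining any unit of replication
    ("pseudo neutral": no rate requirement)."""
    return _expand(master, max_hd, cap_found, engine, params, seed,
                   rate_filter=False)


def _mutant_at_hd(seq: str, hd: int, rng) -> str:
    positions = rng.choice(len(seq), size=hd, replace=False)
    out = list(seq)
    for i in positions:
        out[i] = _BASES.replace(out[i], "")[rng.integers(3)]
    return "".join(out)


def sample_at_hd(master: Genotype, hd_values, engine: FoldEngine,
                 params: EnergyParams = DEFAULT_ENERGY,
                 cap_found: int = 10_000, cap_tries: int = 100_000,
                 seed=0) -> SpectrumResult:
    """Random mutants at each exact Hamming distance, keeping the units of
    replication found.

    At each distance the sampler stops when *cap_found* distinct units have
    been retained or *cap_tries* consecutive draws yield no new unit, then
    moves on to the next distance.
    """
    rng = np.random.default_rng(seed)
    caps_hit: dict = {}
    rows = []
    for hd in hd_values:
        seen = set()
        found = []
        fruitless = 0
        while len(found) < cap_found and fruitless < cap_tries:
            m = _mutant_at_hd(master.plus.sequence, hd, rng)
            key = canonical_strand(m)
            if key in seen:
                fruitless += 1
                continue
            seen.add(key)
            g = genotype_of(m, engine, params)
            if g.func_class is FuncClass.UNIT_OF_REPLICATION:
                found.append(g)
                fruitless = 0
            else:
                fruitless += 1
        if len(found) >= cap_found:
            caps_hit[hd] = len(found)
        rows.append(_layer_stats(hd, found, engine, params, caps_hit, cap_found))
    return SpectrumResult(reference=master.plus.sequence,
                          table=pd.DataFrame(rows), caps_hit=caps_hit)


# -- consensus / master detection -------------------------------------------


def consensus_and_master(population) -> tuple:
    """Per-position plurality consensus and modal (master) sequence.

    Strands are first oriented (sequence vs reverse complement) by minimum
    Hamming distance to the running plurality; ties break lexicographically.
    Returns (consensus, master).
    """
    population = list(population)
    if not population:
        raise ValueError("empty population")
    ref = population[0]

    def orient(seq, against):
        rc = reverse_complement(seq)
        d, drc = hamming(seq, against), hamming(rc, against)
        if d < drc:
            return seq
        if drc < d:
            return rc
        return min(seq, rc)

    oriented = [orient(s, ref) for s in population]
    # one refinement pass against the first-round consensus
    for _ in range(2):
        consensus = "".join(
            sorted(Counter(col).items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            for col in zip(*oriented))
        oriented = [orient(s, consensus) for s in population]
    counts = Counter(oriented)
    top = max(counts.values())
    master = min(s for s, c in counts.items() if c == top)
    return consensus, master


# -- quasispecies network ----------------------------------------------------


def build_network(units, master: str, abundances=None, engine: FoldEngine = None,
                  params: EnergyParams = DEFAULT_ENERGY,
                  compute_neighborhoods: bool = False):
    """Graph of units of replication with edges at genotype HD = 1.

    Nodes are canonical strands annotated with Hamming distance to the
    master, abundance, and (optionally) their own HD=1 class fractions and
    a core-neutral flag (replication rate >= that of the master).
    """
    import networkx as nx

    glist = list(units)
    graph = nx.Graph()
    master_rate = None
    if engine is not None:
        master_rate = replication_rate_proxy(genotype_of(master, engine, params),
                                             params)
    for g in glist:
        key = canonical_strand(g.plus.sequence)
        attrs = {"hd_to_master": genotype_hamming(g.plus.sequence, master),
                 "abundance": (abundances or {}).get(key, 1)}
        if master_rate is not None:
            attrs["core_neutral"] = (replication_rate_proxy(g, params)
                                     >= master_rate)
        if compute_neighborhoods and engine is not None:
            sp = hd1_spectrum(g, engine, params)
            attrs.update({f"frac_{fc.value}": sp.fractions[fc] for fc in FuncClass})
        graph.add_node(key, **attrs)
    keys = list(graph.nodes)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            if genotype_hamming(keys[i], keys[j]) == 1:
                graph.add_edge(keys[i], keys[j])
    return graph
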