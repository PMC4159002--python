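"""Genotypes and the functional classification of their phenotypes.

A genotype is a strand together with its reverse complement, since
replication always produces the complementary sequence.  Each strand
contributes three structural bits (5'-dangling end present, catalytic fold,
3'-dangling end present), so a phenotype coarse-grains to 6 bits and there
are exactly 64 of them.  The classification below is a total function of
those bits:

* a genotype is *viable* (can be replicated) iff both strands carry a
  3'-dangling end;
* a strand is *replicase-like* if it has a 5' tail and the catalytic fold,
  *staller-like* if it has a 5' tail but not the fold, and *inert* with no
  5' tail.

Viable genotypes with at least one replicase-like strand are units of
replication; viable genotypes without one are parasites.  Among nonviable
genotypes: helpers carry a replicase-like strand (and no staller-like one),
stallers a staller-like strand (and no replicase), hybrids one of each, and
junk has no 5' tail on either strand and cannot form complexes at all.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

from .energy import DEFAULT_ENERGY, EnergyParams
from .folding import FoldEngine, StrandProfile, profile
from .seq import reverse_complement

__all__ = [
    "FuncClass", "StrandRole", "Genotype", "reverse_complement",
    "classify", "strand_class", "genotype_of", "class_fractions",
]


class FuncClass(Enum):
    UNIT_OF_REPLICATION = "unit"
    PARASITE = "parasite"
    HELPER = "helper"
    STALLER = "staller"
    JUNK = "junk"
    HYBRID = "hybrid"


class StrandRole(Enum):
    REPLICASE_LIKE = "replicase_like"
    STALLER_LIKE = "staller_like"
    INERT = "inert"


# single-character codes used in grid snapshots
CLASS_CODES = {
    FuncClass.UNIT_OF_REPLICATION: "U",
    FuncClass.PARASITE: "P",
    FuncClass.HELPER: "H",
    FuncClass.STALLER: "S",
    FuncClass.JUNK: "J",
    FuncClass.HYBRID: "Y",
}


def _role(has5: bool, catalytic: bool) -> StrandRole:
    if not has5:
        return StrandRole.INERT
    return StrandRole.REPLICASE_LIKE if catalytic else StrandRole.STALLER_LIKE


def strand_class(prof: StrandProfile) -> StrandRole:
    """Per-strand role, used for field statistics of single strands
    (a hybrid genotype's strands split into helper-like and staller-like)."""
    return _role(prof.has5, prof.catalytic)


def classify(bits) -> FuncClass:
    """Map a 6-bit phenotype to its functional class (total on all 64).

    ``bits`` = (plus.has5, plus.catalytic, plus.has3,
                minus.has5, minus.catalytic, minus.has3).
    """
    p5, pcat, p3, m5, mcat, m3 = (bool(b) for b in bits)
    viable = p3 and m3
    roles = (_role(p5, pcat), _role(m5, mcat))
    any_r = StrandRole.REPLICASE_LIKE in roles
    any_s = StrandRole.STALLER_LIKE in roles
    if viable:
        return FuncClass.UNIT_OF_REPLICATION if any_r else FuncClass.PARASITE
    if any_r and any_s:
        return FuncClass.HYBRID
    if any_r:
        return FuncClass.HELPER
    if any_s:
        return FuncClass.STALLER
    return FuncClass.JUNK


@dataclass(frozen=True)
class Genotype:
    """A plus strand, its reverse complement, and their joint phenotype."""

    plus: StrandProfile
    minus: StrandProfile
    bits: tuple
    func_class: FuncClass

    @property
    def sequence(self) -> str:
        return self.plus.sequence


def genotype_of(seq: str, engine: FoldEngine,
                params: EnergyParams = DEFAULT_ENERGY) -> Genotype:
    """Fold a strand and its reverse complement and classify the pair."""
    plus = profile(seq, engine, params)
    minus = profile(reverse_complement(seq), engine, params)
    bits = plus.bits + minus.bits
    return Genotype(plus=plus, minus=minus, bits=bits, func_class=classify(bits))


def class_fractions(genotypes) -> dict:
    """Fractions of the six functional classes over a list of genotypes."""
    genotypes = list(genotypes)
    if not genotypes:
        raise ValueError("class_fractions requires a nonempty list")
    counts = Counter(g.func_class for g in genotypes)
    n = len(genotypes)
    return {fc: counts.get(fc, 0) / n for fc in FuncClass}
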