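"""Hybridization scoring between dangling ends.

Two molecules form a complex by base-pairing the 5'-dangling end of one
against the 3'-dangling end of the other.  The score of a configuration is
the minimum, over all ungapped sliding alignments of the two tails, of the
summed base-pair contributions (G-C: -0.15, A-U: -0.10, G-U: -0.05,
everything else 0).  Binding probability follows P = 1 - exp(Gmin), and the
two possible orientations of a pair of molecules are normalized against one
another when their probabilities sum above 1.

All default contributions are multiples of 0.05, so scores are compared to
thresholds exactly on rational arithmetic: a tail scoring exactly -0.75 must
count as reaching the -0.75 dangling-end threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

from .seq import check_alphabet, reverse_complement


def _as_fraction(x: float) -> Fraction:
    # str() of a float like -0.15 is its shortest decimal form, which is the
    # intended exact value for the thresholds used here.
    return Fraction(str(x))


@dataclass(frozen=True)
class EnergyParams:
    """Pair contributions and the dangling-end recognition threshold.

    Contributions are dimensionless pseudo-energies; more negative means
    stronger binding.
    """

    gc_contribution: float = -0.15
    au_contribution: float = -0.10
    gu_contribution: float = -0.05
    other_contribution: float = 0.0
    tail_threshold: float = -0.75

    def __post_init__(self):
        for name in ("gc_contribution", "au_contribution", "gu_contribution",
                     "other_contribution"):
            if getattr(self, name) > 0:
                raise ValueError(f"{name} must be <= 0")
        if self.tail_threshold >= 0:
            raise ValueError("tail_threshold must be negative")

    def pair_table(self) -> dict:
        gc = _as_fraction(self.gc_contribution)
        au = _as_fraction(self.au_contribution)
        gu = _as_fraction(self.gu_contribution)
        return {
            frozenset("GC"): gc,
            frozenset("AU"): au,
            frozenset("GU"): gu,
        }


DEFAULT_ENERGY = EnergyParams()


@dataclass(frozen=True)
class BindingResult:
    """Association/dissociation probabilities for the two orientations of a
    molecule pair: X presenting its 5' tail against Y's 3' tail, and the
    reverse."""

    g_xy: float
    g_yx: float
    p_xy: float
    p_yx: float
    k1_xy: float
    k1_yx: float
    k2_xy: float
    k2_yx: float


def pair_contribution(b1: str, b2: str, params: EnergyParams = DEFAULT_ENERGY) -> float:
    """Contribution of pairing base *b1* with *b2* (symmetric)."""
    return float(_pair_contribution_frac(b1, b2, params))


def _pair_contribution_frac(b1: str, b2: str, params: EnergyParams) -> Fraction:
    check_alphabet(b1)
    check_alphabet(b2)
    if len(b1) != 1 or len(b2) != 1:
        raise ValueError("pair_contribution expects single nucleotides")
    table = params.pair_table()
    return table.get(frozenset((b1, b2)), _as_fraction(params.other_contribution))


def _gmin_frac(tail5: str, tail3: str, params: EnergyParams) -> Fraction:
    """Exact-arithmetic minimum sliding-alignment score.

    tail5 is read 5'->3'; tail3 is read 5'->3' and paired antiparallel:
    position i of tail5 pairs position (len(tail3) - 1 - i - offset) of
    tail3.  Gaps are not allowed; mismatched positions contribute
    ``other_contribution`` (0 by default), so the per-offset total equals the
    best contiguous matching stretch at that offset.
    """
    check_alphabet(tail5)
    check_alphabet(tail3)
    n5, n3 = len(tail5), len(tail3)
    if n5 == 0 or n3 == 0:
        return Fraction(0)
    table = params.pair_table()
    other = _as_fraction(params.other_contribution)
    best = Fraction(0)
    for offset in range(-(n5 - 1), n3):
        score = Fraction(0)
        overlapped = False
        for i in range(n5):
            j = n3 - 1 - i - offset
            if 0 <= j < n3:
                overlapped = True
                score += table.get(frozenset((tail5[i], tail3[j])), other)
        if overlapped and score < best:
            best = score
    return best


def gmin(tail5: str, tail3: str, params: EnergyParams = DEFAULT_ENERGY) -> float:
    """Minimum ungapped sliding-alignment score of two dangling ends.

    Returns 0 if either tail is empty or no offset gives a negative total.
    """
    return float(_gmin_frac(tail5, tail3, params))


def binding_probability(g: float) -> float:
    """P = 1 - exp(G) for a (non-positive) hybridization score."""
    if g > 0:
        raise ValueError("binding score must be <= 0")
    return -math.expm1(g)


def complex_rates(x5: str, x3: str, y5: str, y3: str,
                  params: EnergyParams = DEFAULT_ENERGY) -> BindingResult:
    """Association/dissociation probabilities for molecules X and Y.

    Both orientations are scored; if the two binding probabilities sum above
    1 they are normalized (k1_xy = p_xy / (p_xy + p_yx)); the dissociation
    probability of a realized configuration is k2 = 1 - k1.
    """
    g_xy = gmin(x5, y3, params)
    g_yx = gmin(y5, x3, params)
    p_xy = binding_probability(g_xy)
    p_yx = binding_probability(g_yx)
    if p_xy + p_yx > 1.0:
        tot = p_xy + p_yx
        k1_xy, k1_yx = p_xy / tot, p_yx / tot
    else:
        k1_xy, k1_yx = p_xy, p_yx
    return BindingResult(g_xy=g_xy, g_yx=g_yx, p_xy=p_xy, p_yx=p_yx,
                         k1_xy=k1_xy, k1_yx=k1_yx,
                         k2_xy=1.0 - k1_xy, k2_yx=1.0 - k1_yx)


@lru_cache(maxsize=200_000)
def _tail_present_cached(tail: str, params: EnergyParams) -> bool:
    if not tail:
        return False
    g = _gmin_frac(tail, reverse_complement(tail), params)
    return g <= _as_fraction(params.tail_threshold)


def tail_present(tail: str, params: EnergyParams = DEFAULT_ENERGY) -> bool:
    """Whether a dangling end is long/strong enough to count as present.

    The perfectly complementary stretch is generated and the hybridization
    score computed; the tail is present iff that score reaches the
    recognition threshold (default -0.75, binding probability ~0.5).  The
    comparison is exact, so five G-C pairs (score exactly -0.75) qualify
    while seven A-U pairs (-0.70) do not.
    """
    return _tail_present_cached(tail, params)
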