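"""Secondary-structure engines, coarse-grained structure, strand profiles.

Folding is behind a small contract (``FoldEngine``): the production engine
wraps ViennaRNA's minimum-free-energy fold; a deterministic base-pair
maximization engine (Nussinov-style, minimum hairpin size 3, leftmost-pair
tie-breaking) is provided so every downstream component can be exercised
without the thermodynamic engine.  Which engine folded a sequence matters
for any statistic over genotype space, so engines carry an identity string
recorded in outputs.

The catalytic phenotype is an exact match of the coarse-grained (Shapiro)
structure against ``((((H)S)((H)S)M)S)``: a stem enclosing a multiloop that
connects two stem-hairpins.  Exterior dangling regions are excluded from
the coarse string, so 5'/3' tails never affect the match.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

from .energy import DEFAULT_ENERGY, EnergyParams, tail_present
from .seq import check_alphabet

CATALYTIC_COARSE = "((((H)S)((H)S)M)S)"

_PAIRABLE = {frozenset("AU"), frozenset("GC")}


@runtime_checkable
class FoldEngine(Protocol):
    """Contract: deterministic sequence -> dot-bracket of equal length."""

    name: str

    def fold(self, seq: str) -> str: ...


_VIENNA_LOADED_PARAMS = [None]


class ViennaFoldEngine:
    """Minimum-free-energy folding via the ViennaRNA python bindings.

    Defaults to the Turner-1999 energy parameters with dangle model 1,
    which emulates the behaviour of the 1.x generation of the Vienna
    package; genotype-space statistics (e.g. the fraction of random
    sequences folding into a given coarse structure) depend noticeably on
    this choice.  Pass ``param_set="turner2004"``/``dangles=2`` for the
    modern defaults.
    """

    _LOADERS = {"turner1999": "params_load_RNA_Turner1999",
                "turner2004": "params_load_RNA_Turner2004"}

    def __init__(self, param_set: str = "turner1999", dangles: int = 1):
        import RNA  # deferred: optional dependency

        if param_set not in self._LOADERS:
            raise ValueError(f"unknown parameter set {param_set!r}")
        self._RNA = RNA
        self.param_set = param_set
        self._md = RNA.md()
        self._md.dangles = dangles
        self.name = f"vienna-{RNA.__version__}-{param_set}-d{dangles}"

    def _ensure_params(self):
        # the energy parameter tables are process-global in ViennaRNA
        if _VIENNA_LOADED_PARAMS[0] != self.param_set:
            getattr(self._RNA, self._LOADERS[self.param_set])()
            _VIENNA_LOADED_PARAMS[0] = self.param_set

    def fold(self, seq: str) -> str:
        check_alphabet(seq)
        self._ensure_params()
        structure, _energy = self._RNA.fold_compound(seq, self._md).mfe()
        return structure


class NussinovFoldEngine:
    """Deterministic base-pair maximization fallback.

    Watson-Crick pairs only (wobble excluded: pair maximization with
    wobble pairs leaves almost no dangling ends on 4-letter sequences,
    collapsing the phenotype space this engine exists to exercise);
    hairpin loops enclose at least 3 unpaired bases; ties are broken by
    preferring to leave the rightmost base unpaired, otherwise by the
    leftmost pairing partner.  Fully deterministic and
    platform-independent, which makes it the engine of choice for tests
    of classification logic.
    """

    name = "nussinov-maxpair"

    def __init__(self, min_hairpin: int = 3):
        self.min_hairpin = min_hairpin
        self._cache: dict[str, str] = {}

    _PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}

    def fold(self, seq: str) -> str:
        check_alphabet(seq)
        cached = self._cache.get(seq)
        if cached is not None:
            return cached
        import bisect

        n = len(seq)
        h = self.min_hairpin
        # candidate pairing partners for each closing base, by letter
        positions = {b: [i for i, c in enumerate(seq) if c == b] for b in "ACGU"}

        def partners(i, j):
            pos = positions[self._PARTNER[seq[j]]]
            lo = bisect.bisect_left(pos, i)
            hi = bisect.bisect_left(pos, j - h)
            return pos[lo:hi]

        M = [[0] * n for _ in range(n)]
        for span in range(h + 1, n):
            for i in range(0, n - span):
                j = i + span
                row_i = M[i]
                best = row_i[j - 1]
                for k in partners(i, j):
                    cand = (row_i[k - 1] if k > i else 0) + \
                           (M[k + 1][j - 1] if k + 1 <= j - 1 else 0) + 1
                    if cand > best:
                        best = cand
                row_i[j] = best
        structure = ["."] * n
        stack = [(0, n - 1)]
        while stack:
            i, j = stack.pop()
            if j - i <= h:
                continue
            if M[i][j] == M[i][j - 1]:
                stack.append((i, j - 1))
                continue
            for k in partners(i, j):
                cand = (M[i][k - 1] if k > i else 0) + \
                       (M[k + 1][j - 1] if k + 1 <= j - 1 else 0) + 1
                if cand == M[i][j]:
                    structure[k] = "("
                    structure[j] = ")"
                    if k > i:
                        stack.append((i, k - 1))
                    stack.append((k + 1, j - 1))
                    break
        result = "".join(structure)
        self._cache[seq] = result
        return result


def get_engine(kind: str) -> FoldEngine:
    """Engine factory for the config key [fold].engine in {mfe, fallback}."""
    if kind == "mfe":
        return ViennaFoldEngine()
    if kind == "fallback":
        return NussinovFoldEngine()
    raise ValueError(f"unknown fold engine {kind!r}")


def pair_table(dotbracket: str) -> list:
    """Map position -> paired position (or -1); raises on unbalanced input."""
    table = [-1] * len(dotbracket)
    stack = []
    for i, c in enumerate(dotbracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced structure at position {i}")
            j = stack.pop()
            table[i], table[j] = j, i
        elif c != ".":
            raise ValueError(f"invalid structure character {c!r}")
    if stack:
        raise ValueError("unbalanced structure: unclosed '('")
    return table


def _helix_string(i: int, j: int, table: list) -> str:
    """Coarse string for the helix whose outermost pair is (i, j)."""
    # extend the stack of directly nested pairs
    while table[i + 1] == j - 1 and i + 1 < j - 1:
        i, j = i + 1, j - 1
    # inspect the loop closed by (i, j)
    children = []
    unpaired = 0
    k = i + 1
    while k < j:
        if table[k] > k:
            children.append((k, table[k]))
            k = table[k] + 1
        else:
            unpaired += 1
            k += 1
    if not children:
        inner = "(H)"
    elif len(children) == 1:
        (a, b) = children[0]
        left = a - (i + 1)
        right = (j - 1) - b
        label = "B" if (left == 0 or right == 0) else "I"
        inner = "(" + _helix_string(a, b, table) + label + ")"
    else:
        inner = "(" + "".join(_helix_string(a, b, table) for a, b in children) + "M)"
    return "(" + inner + "S)"


def coarse_shapiro(dotbracket: str) -> str:
    """Coarse-grained Shapiro string of a dot-bracket structure.

    Nodes: H hairpin, S maximal stem, M multiloop, B bulge, I interior
    loop; no size annotations and no exterior node.  A maximal stem is a
    run of directly stacked pairs; a bulge or interior loop splits stems.
    An open chain yields the empty string; several exterior helices are
    concatenated.
    """
    table = pair_table(dotbracket)
    out = []
    k = 0
    n = len(dotbracket)
    while k < n:
        if table[k] > k:
            out.append(_helix_string(k, table[k], table))
            k = table[k] + 1
        else:
            k += 1
    return "".join(out)


def is_catalytic(dotbracket: str) -> bool:
    """Whether a structure matches the catalytic coarse structure exactly."""
    return coarse_shapiro(dotbracket) == CATALYTIC_COARSE


@dataclass(frozen=True)
class StrandProfile:
    """One strand with its structural annotation.

    ``tail5``/``tail3`` are the maximal unpaired prefix/suffix of the MFE
    structure (the whole sequence for an open chain); ``has5``/``has3``
    apply the dangling-end recognition threshold; ``catalytic`` is the
    coarse-structure match.
    """

    sequence: str
    dotbracket: str
    coarse: str
    tail5: str
    tail3: str
    catalytic: bool
    has5: bool
    has3: bool

    @property
    def bits(self) -> tuple:
        return (self.has5, self.catalytic, self.has3)


_PROFILE_CACHE: dict = {}


def profile(seq: str, engine: FoldEngine,
            params: EnergyParams = DEFAULT_ENERGY) -> StrandProfile:
    """Fold a strand and annotate tails, dangling-end bits and catalysis.

    Results are cached by (engine identity, sequence, params): the grid
    simulator and the neighborhood searches revisit the same sequences
    constantly and must never fold one twice.
    """
    key = (engine.name, seq, params)
    hit = _PROFILE_CACHE.get(key)
    if hit is not None:
        return hit
    check_alphabet(seq)
    db = engine.fold(seq)
    if len(db) != len(seq):
        raise ValueError(f"engine {engine.name} returned structure of wrong length")
    coarse = coarse_shapiro(db)
    if "(" not in db:
        tail5 = tail3 = seq
    else:
        n5 = len(db) - len(db.lstrip("."))
        n3 = len(db) - len(db.rstrip("."))
        tail5 = seq[:n5]
        tail3 = seq[len(seq) - n3:] if n3 else ""
    prof = StrandProfile(
        sequence=seq, dotbracket=db, coarse=coarse,
        tail5=tail5, tail3=tail3,
        catalytic=(coarse == CATALYTIC_COARSE),
        has5=tail_present(tail5, params),
        has3=tail_present(tail3, params),
    )
    _PROFILE_CACHE[key] = prof
    return prof


def clear_profile_cache():
    _PROFILE_CACHE.clear()
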