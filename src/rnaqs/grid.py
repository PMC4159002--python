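"""Spatial individual-based Monte Carlo simulator.

Molecules live on a toroidal square lattice, at most one per cell.  One
Monte Carlo step visits all cells in a fresh random permutation and, for
each occupied cell, runs four phases in order:

1. complex formation (with a random free neighbor, orientation chosen
   proportionally to the association probabilities ``k1``) or complex
   dissociation with probability ``k2``;
2. replication: if the visited molecule presents its 5' end in a complex
   and is catalytic, with probability ``kappa`` the mutated reverse
   complement of its partner (the template) is placed on a random empty
   cell adjacent to the complex, and the complex breaks;
3. diffusion: one random-walk step (complexes move rigidly and have a
   small probability of not moving);
4. decay with probability ``d`` (a decayed partner frees the survivor).

Only substitutions are implemented; sequence length is constant.  In the
evolvable-mutation-rate mode each molecule carries its own per-base
substitution probability, and every mutated copy perturbs it by a small
random number (positive-only or unbiased), so lineages can drift to higher
mutation rates during an evolutionary run.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .energy import DEFAULT_ENERGY, EnergyParams, complex_rates
from .folding import FoldEngine
from .phenotype import CLASS_CODES, FuncClass, Genotype, genotype_of
from .seq import genotype_hamming, reverse_complement

MOORE = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))
VON_NEUMANN = ((-1, 0), (0, -1), (0, 1), (1, 0))

_BASES = "ACGU"
# alternatives[b] = the three bases != b
_ALTERNATIVES = {b: _BASES.replace(b, "") for b in _BASES}


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters; the defaults are the reference setting
    (512x512 toroidal grid, 50-nt sequences, kappa=1, d=0.03)."""

    width: int = 512
    height: int = 512
    seq_length: int = 50
    replication_rate: float = 1.0       # kappa
    decay_rate: float = 0.03            # d
    complex_no_move_prob: float = 0.1
    mu: float = 0.015                   # per-base substitution probability
    evolve_mu: bool = False
    mu_mode: str = "positive"           # or "unbiased"
    mu_step: float = 5e-4               # epsilon, half-width of the mu kick
    neighborhood: str = "moore"         # or "von_neumann"

    def __post_init__(self):
        for name in ("replication_rate", "decay_rate", "complex_no_move_prob", "mu"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.mu_mode not in ("positive", "unbiased"):
            raise ValueError("mu_mode must be 'positive' or 'unbiased'")
        if self.neighborhood not in ("moore", "von_neumann"):
            raise ValueError("neighborhood must be 'moore' or 'von_neumann'")


class Molecule:
    """One RNA molecule on the grid (possibly half of a complex)."""

    __slots__ = ("id", "sequence", "mu", "pos", "partner", "role", "k2",
                 "lineage", "parent_id", "birth_step", "inert")

    def __init__(self, mol_id, sequence, mu, pos, lineage=0, parent_id=-1,
                 birth_step=0):
        self.id = mol_id
        self.sequence = sequence
        self.mu = mu
        self.pos = pos
        self.partner = None       # Molecule or None
        self.role = None          # "5p" (presents 5' tail) or "3p"
        self.k2 = 0.0             # dissociation prob of the realized complex
        self.lineage = lineage
        self.parent_id = parent_id
        self.birth_step = birth_step
        self.inert = False        # set by the class_to_junk intervention

    def __repr__(self):  # pragma: no cover
        state = "free" if self.partner is None else f"complex[{self.role}]"
        return f"<Molecule {self.id} at {self.pos} {state}>"


def mutate_copy(template: str, mu: float, rng) -> tuple:
    """Reverse complement of *template* with iid substitutions at rate *mu*.

    Each substituted position gets one of the three alternative bases
    uniformly.  Returns (sequence, number of substitutions).
    """
    copy = list(reverse_complement(template))
    if mu <= 0.0:
        return "".join(copy), 0
    hits = np.flatnonzero(rng.random(len(copy)) < mu)
    for i in hits:
        copy[i] = _ALTERNATIVES[copy[i]][rng.integers(3)]
    return "".join(copy), len(hits)


def evolve_mu(parent_mu: float, rng, params: SimParams) -> float:
    """Offspring mutation rate after a mutated replication event."""
    if params.mu_mode == "positive":
        draw = rng.uniform(0.0, params.mu_step)
    else:
        draw = rng.uniform(-params.mu_step, params.mu_step)
    return float(min(1.0, max(0.0, parent_mu + draw)))


class World:
    """Toroidal lattice of molecules with parameters, RNG and observers."""

    def __init__(self, params: SimParams, engine: FoldEngine,
                 energy: EnergyParams = DEFAULT_ENERGY, seed: int = 0):
        self.params = params
        self.engine = engine
        self.energy = energy
        self.rng = np.random.default_rng(seed)
        self.grid: dict = {}
        self.step_count = 0
        self.observers: list = []
        self.interventions: list = []
        self.birth_log: list = []      # (id, parent_id, birth_step, lineage)
        self.death_count = 0
        self._next_id = 0
        self._offsets = MOORE if params.neighborhood == "moore" else VON_NEUMANN
        self._coords = [(x, y) for y in range(params.height)
                        for x in range(params.width)]
        self._genotypes: dict = {}

    # -- genotype bookkeeping ------------------------------------------------

    def genotype(self, seq: str) -> Genotype:
        g = self._genotypes.get(seq)
        if g is None:
            g = genotype_of(seq, self.engine, self.energy)
            self._genotypes[seq] = g
        return g

    def func_class(self, mol: Molecule) -> FuncClass:
        if mol.inert:
            return FuncClass.JUNK
        return self.genotype(mol.sequence).func_class

    # -- population setup ----------------------------------------------------

    def add_molecule(self, seq: str, pos, mu=None, lineage=0, parent_id=-1) -> Molecule:
        if pos in self.grid:
            raise ValueError(f"cell {pos} already occupied")
        mol = Molecule(self._next_id, seq, self.params.mu if mu is None else mu,
                       pos, lineage=lineage, parent_id=parent_id,
                       birth_step=self.step_count)
        self._next_id += 1
        self.grid[pos] = mol
        self.birth_log.append((mol.id, parent_id, self.step_count, lineage))
        return mol

    def populate(self, sequences, density=0.5, region=None, lineage=0):
        """Seed molecules (cycled from *sequences*) on random empty cells of
        *region* (default: whole grid) at the given density."""
        if not sequences:
            raise ValueError("populate requires a nonempty sequence list")
        cells = [c for c in (region if region is not None else self._coords)
                 if c not in self.grid]
        k = int(round(density * len(cells)))
        chosen = self.rng.permutation(len(cells))[:k]
        for n, idx in enumerate(chosen):
            self.add_molecule(sequences[n % len(sequences)], cells[idx],
                              lineage=lineage)

    # -- neighborhood helpers ------------------------------------------------

    def _wrap(self, x, y):
        return (x % self.params.width, y % self.params.height)

    def neighbors(self, pos):
        x, y = pos
        return [self._wrap(x + dx, y + dy) for dx, dy in self._offsets]

    # -- complex management --------------------------------------------------

    def _form_complex(self, presenter5: Molecule, presenter3: Molecule, k2: float):
        presenter5.partner, presenter5.role, presenter5.k2 = presenter3, "5p", k2
        presenter3.partner, presenter3.role, presenter3.k2 = presenter5, "3p", k2

    def _break_complex(self, mol: Molecule):
        other = mol.partner
        mol.partner = mol.role = None
        if other is not None:
            other.partner = other.role = None

    def _remove(self, mol: Molecule):
        self._break_complex(mol)
        del self.grid[mol.pos]
        mol.pos = None
        self.death_count += 1

    # -- the Monte Carlo step ------------------------------------------------

    def mc_step(self):
        p = self.params
        rng = self.rng
        for idx in rng.permutation(len(self._coords)):
            pos = self._coords[idx]
            mol = self.grid.get(pos)
            if mol is None:
                continue
            # phase 1: complex formation / dissociation
            if mol.partner is None:
                if not mol.inert:
                    self._try_form_complex(mol)
            elif mol.role == "5p":
                if rng.random() < mol.k2:
                    self._break_complex(mol)
            # phase 2: replication
            if (mol.partner is not None and mol.role == "5p"
                    and self.genotype(mol.sequence).plus.catalytic
                    and not mol.inert):
                if rng.random() < p.replication_rate:
                    self._replicate(mol)
            # phase 3: diffusion
            if mol.pos is not None:
                self._diffuse(mol)
            # phase 4: decay
            if mol.pos is not None and rng.random() < p.decay_rate:
                self._remove(mol)
        self.step_count += 1
        for kind, target in self.interventions:
            self._apply_intervention(kind, target)
        for interval, obs in self.observers:
            if self.step_count % interval == 0:
                obs.observe(self)

    def run(self, steps: int):
        for _ in range(steps):
            self.mc_step()

    def _try_form_complex(self, mol: Molecule):
        rng = self.rng
        candidates = []
        for npos in self.neighbors(mol.pos):
            other = self.grid.get(npos)
            if other is not None and other.partner is None and not other.inert:
                candidates.append(other)
        if not candidates:
            return
        other = candidates[rng.integers(len(candidates))]
        gx = self.genotype(mol.sequence).plus
        gy = self.genotype(other.sequence).plus
        rates = complex_rates(gx.tail5, gx.tail3, gy.tail5, gy.tail3, self.energy)
        u = rng.random()
        if u < rates.k1_xy:
            self._form_complex(mol, other, rates.k2_xy)
        elif u < rates.k1_xy + rates.k1_yx:
            self._form_complex(other, mol, rates.k2_yx)

    def _replicate(self, replicase: Molecule):
        rng = self.rng
        template = replicase.partner
        empties = []
        seen = set()
        for anchor in (replicase.pos, template.pos):
            for npos in self.neighbors(anchor):
                if npos not in seen and npos not in self.grid:
                    seen.add(npos)
                    empties.append(npos)
        if not empties:
            return
        target = empties[rng.integers(len(empties))]
        child_seq, n_subs = mutate_copy(template.sequence, template.mu, rng)
        child_mu = template.mu
        if self.params.evolve_mu and n_subs > 0:
            child_mu = evolve_mu(template.mu, rng, self.params)
        self.add_molecule(child_seq, target, mu=child_mu,
                          lineage=template.lineage, parent_id=template.id)
        self._break_complex(replicase)

    def _diffuse(self, mol: Molecule):
        rng = self.rng
        if mol.partner is None:
            dx, dy = self._offsets[rng.integers(len(self._offsets))]
            target = self._wrap(mol.pos[0] + dx, mol.pos[1] + dy)
            if target not in self.grid:
                del self.grid[mol.pos]
                mol.pos = target
                self.grid[target] = mol
        elif mol.role == "5p":
            # complexes diffuse more slowly: small chance of not moving
            if rng.random() < self.params.complex_no_move_prob:
                return
            other = mol.partner
            dx, dy = self._offsets[rng.integers(len(self._offsets))]
            t1 = self._wrap(mol.pos[0] + dx, mol.pos[1] + dy)
            t2 = self._wrap(other.pos[0] + dx, other.pos[1] + dy)
            pair = {mol.pos, other.pos}
            ok1 = t1 not in self.grid or t1 in pair
            ok2 = t2 not in self.grid or t2 in pair
            if ok1 and ok2:
                del self.grid[mol.pos]
                del self.grid[other.pos]
                mol.pos, other.pos = t1, t2
                self.grid[t1] = mol
                self.grid[t2] = other

    # -- interventions -------------------------------------------------------

    def add_intervention(self, kind: str, target: FuncClass):
        """Schedule a per-step knockout: 'remove_class' deletes every
        molecule of the target class, 'class_to_junk' makes them inert
        (unable to bind)."""
        if kind not in ("remove_class", "class_to_junk"):
            raise ValueError(f"unknown intervention {kind!r}")
        if not isinstance(target, FuncClass):
            raise ValueError("intervention target must be a FuncClass")
        self.interventions.append((kind, target))

    def _apply_intervention(self, kind, target):
        victims = [m for m in list(self.grid.values())
                   if not m.inert
                   and self.genotype(m.sequence).func_class is target]
        for m in victims:
            if kind == "remove_class":
                self._remove(m)
            else:
                m.inert = True
                self._break_complex(m)

    # -- observation ---------------------------------------------------------

    def add_observer(self, observer, interval: int = 1):
        self.observers.append((interval, observer))

    def molecules(self):
        return list(self.grid.values())

    def class_counts(self) -> Counter:
        return Counter(self.func_class(m) for m in self.grid.values())

    def snapshot(self) -> list:
        """Plain-text grid of per-cell class codes ('.' = empty)."""
        rows = []
        for y in range(self.params.height):
            row = []
            for x in range(self.params.width):
                mol = self.grid.get((x, y))
                row.append("." if mol is None else CLASS_CODES[self.func_class(mol)])
            rows.append("".join(row))
        return rows

    def check_invariants(self):
        """Occupancy and complex-adjacency invariants (used by tests)."""
        w, h = self.params.width, self.params.height
        for pos, mol in self.grid.items():
            assert mol.pos == pos
            if mol.partner is not None:
                assert mol.partner.partner is mol
                assert {mol.role, mol.partner.role} == {"5p", "3p"}
                dx = min((mol.pos[0] - mol.partner.pos[0]) % w,
                         (mol.partner.pos[0] - mol.pos[0]) % w)
                dy = min((mol.pos[1] - mol.partner.pos[1]) % h,
                         (mol.partner.pos[1] - mol.pos[1]) % h)
                assert dx <= 1 and dy <= 1 and (dx, dy) != (0, 0)


# -- competition experiments ----------------------------------------------

def init_competition(world: World, pop_a, pop_b, density: float = 0.5) -> World:
    """Seed the left half of the field from *pop_a* (lineage 0) and the
    right half from *pop_b* (lineage 1)."""
    if not pop_a or not pop_b:
        raise ValueError("both populations must be nonempty")
    w, h = world.params.width, world.params.height
    left = [(x, y) for y in range(h) for x in range(w // 2)]
    right = [(x, y) for y in range(h) for x in range(w // 2, w)]
    world.populate(pop_a, density=density, region=left, lineage=0)
    world.populate(pop_b, density=density, region=right, lineage=1)
    return world


def lineage_counts(world: World) -> Counter:
    return Counter(m.lineage for m in world.grid.values())


# -- observers -------------------------------------------------------------

class AbundanceObserver:
    """Per-class molecule counts at each sampling time."""

    def __init__(self):
        self.records = []

    def observe(self, world: World):
        counts = world.class_counts()
        rec = {"step": world.step_count,
               "total": len(world.grid),
               "complexed": sum(m.partner is not None for m in world.grid.values())}
        for fc in FuncClass:
            rec[fc.value] = counts.get(fc, 0)
        self.records.append(rec)

    def frame(self):
        import pandas as pd

        return pd.DataFrame(self.records)


class HDHistogramObserver:
    """Histogram of Hamming distances to a reference sequence.

    The distance of a molecule is min(HD(seq, ref), HD(revcomp(seq), ref)),
    so a molecule carrying the reference's complementary strand lands in
    bin 0.
    """

    def __init__(self, reference: str):
        self.reference = reference
        self.records = []   # (step, Counter)

    def observe(self, world: World):
        hist = Counter(genotype_hamming(m.sequence, self.reference)
                       for m in world.grid.values())
        self.records.append((world.step_count, hist))

    def frame(self):
        import pandas as pd

        rows = []
        for step, hist in self.records:
            for hd, n in sorted(hist.items()):
                rows.append({"step": step, "hd": hd, "count": n})
        return pd.DataFrame(rows, columns=["step", "hd", "count"])


class SnapshotObserver:
    def __init__(self):
        self.records = []   # (step, list of row strings)

    def observe(self, world: World):
        self.records.append((world.step_count, world.snapshot()))


class AncestryObserver:
    """Edges of the ancestry forest: one row per birth since the last
    observation (child id, parent id, birth step, lineage)."""

    def __init__(self):
        self.records = []
        self._seen = 0

    def observe(self, world: World):
        new = world.birth_log[self._seen:]
        self._seen = len(world.birth_log)
        self.records.extend(new)

    def frame(self):
        import pandas as pd

        return pd.DataFrame(self.records,
                            columns=["id", "parent_id", "birth_step", "lineage"])
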