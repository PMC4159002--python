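# rnaqs

Eco-evolutionary dynamics of RNA-like replicator quasispecies.

`rnaqs` is a toolkit for studying populations of short (50-nt) RNA-like
replicators whose phenotype is their secondary structure. A strand is a
*replicase* if it folds into a fixed coarse-grained structure
(`((((H)S)((H)S)M)S)` in Shapiro notation — a stem enclosing a multiloop
with two hairpins) and carries a 5'-dangling end; molecules bind by
hybridizing complementary dangling ends, and a bound replicase copies its
partner into adjacent empty space with per-base mutation probability μ.
Because a genotype is a strand together with its reverse complement, six
structural bits (5' end, catalytic fold, 3' end — per strand) classify
every genotype into one of six functional classes: **units of
replication**, **parasites**, **helpers**, **stallers**, **junk** and
**hybrids**. Around a master sequence, the balance of these classes in
the mutational neighborhood — the neutrality λ (fraction of the 3ν
single-substitution mutants that remain units), the helper fraction λ_H,
the staller fraction λ_S — decides whether a quasispecies persists near
the error threshold.

The package provides, as a library with a thin `rnaqs` CLI on top:

* the dangling-end hybridization model (G–C −0.15, A–U −0.10, G–U −0.05;
  P = 1 − exp(G_min); orientation normalization, k2 = 1 − k1);
* folding behind a pluggable engine (ViennaRNA MFE, configured by default
  to emulate the 1.x parameter generation; plus a deterministic
  base-pair-maximization fallback for engine-free testing), coarse
  Shapiro structures and the catalytic-structure test;
* the 64-phenotype functional classification;
* a spatial Monte Carlo simulator on a toroidal lattice (complex
  formation/dissociation, replication, diffusion, decay, evolvable
  mutation rates, class knockouts, half-field competition experiments,
  observers);
* mutational-neighborhood analysis (HD=1 spectra, tails-only spectra,
  core-/pseudo-neutral expansions, sampling at larger distances, random
  screening, consensus/master detection, quasispecies networks);
* an evolutionary optimizer for replication rate (the no-ecology null
  model);
* mass-action ODE models of the replicator ecology (helpers scheme and
  stallers scheme) with integration, equilibrium continuation and
  bifurcation detection.

See `docs/methods.md` for the model details and numerical choices.

## A worked example

Classify a designed unit of replication and map its mutational
neighborhood with the deterministic fallback engine:

```python
from rnaqs import genotype_of, NussinovFoldEngine
from rnaqs.spectrum import hd1_spectrum

UNIT = "CCCCCUUUUUUUAACCCCUUAACCAAUUCCCCAAUUCCAAAAACCCCCCC"
engine = NussinovFoldEngine()
g = genotype_of(UNIT, engine)
print(g.func_class.value, g.plus.dotbracket)
sp = hd1_spectrum(g, engine)
print(f"lambda = {sp.lambda_neutral:.3f}")
for fc, frac in sp.fractions.items():
    print(f"{fc.value:9s} {frac:.3f}")
```

prints

```
unit .....(((((((((....))))..((((....))))..))))).......
lambda = 0.467
unit      0.467
parasite  0.400
helper    0.067
staller   0.000
junk      0.067
hybrid    0.000
```

i.e. 47% of the 150 single-substitution mutants of this genotype are
still units of replication, 40% lose the catalytic fold but stay
replicable (parasites — the dangerous mutant class), and ~7% each
replicate others without being replicable themselves (helpers) or go
inert (junk). The `examples/` directory has one short script per
capability: classification, neighborhoods, the spatial simulation, the
ODE regime structure, and the replication-rate optimizer.

Command-line equivalents:

```
rnaqs classify units.fasta
rnaqs neighborhood units.fasta --method hd1
rnaqs simulate --inoculum units.fasta --steps 1000 --grid-size 64 --seed 1
rnaqs ode --scheme 1 --free-param mu --range 0.05:0.5:0.01 --lam 0.25
```

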