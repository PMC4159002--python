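# Methods

`rnaqs` models populations of 50-nt RNA-like replicators whose phenotype
is read off their secondary structure, and the ecology that emerges from
their mutants. This note documents the model, the numerical choices, and
what the synthetic experiments do and do not show.

## The chemistry: dangling-end hybridization

Two molecules form a complex by base-pairing the 5'-dangling end of one
against the 3'-dangling end of the other. The score of a configuration is
the minimum over all ungapped sliding alignments of the summed pair
contributions (G–C −0.15, A–U −0.10, G–U −0.05, all else 0; dimensionless
pseudo-energies). Binding probability is P = 1 − exp(G_min). Both
orientations of a molecule pair are scored; when the two probabilities sum
above 1 they are normalized, and the dissociation probability of a bound
configuration is k2 = 1 − k1. Five G–C pairs (G = −0.75, P ≈ 0.53) or
seven A–U pairs (−0.70) are the least that make binding more likely than
dissociation.

A dangling end "counts" (for phenotype classification) if its score
against its own perfect complement reaches −0.75. All default
contributions are multiples of 0.05, so threshold comparisons are done in
exact rational arithmetic: a tail scoring exactly −0.75 is present, one
scoring −0.70 is not. Floating-point comparison would misclassify exactly
the most important boundary case (the all-C 5-mer tail).

## Folding and the catalytic phenotype

A strand is catalytic iff its minimum-free-energy structure coarse-grains
(Shapiro notation, nodes H/S/M/B/I without size annotations, exterior
regions excluded) to exactly `((((H)S)((H)S)M)S)`: a stem enclosing a
multiloop connecting two stem–hairpins. Any bulge or interior loop in the
core disqualifies; 5'/3' tails never affect the match.

Folding is behind a small engine contract:

* **MFE engine** (ViennaRNA): defaults to Turner-1999 parameters with
  dangle model 1, emulating the 1.x generation of the Vienna package.
  This choice matters: genotype-space statistics shift several-fold
  between parameter generations. Under Turner-1999/d1 a screen of random
  50-mers yields unit-of-replication rates of the order of a few per ten
  thousand, and the classic optimized replicator sequences are catalytic
  on both strands; under the modern Turner-2004/d2 defaults both change
  substantially. `ViennaFoldEngine(param_set="turner2004", dangles=2)`
  selects the modern behaviour.
* **fallback engine**: deterministic Nussinov-style base-pair
  maximization (Watson-Crick pairs only, hairpin loops ≥ 3, leftmost-pair
  tie-breaking). It is not thermodynamic; it exists so that every
  downstream component — classification, spectra, the simulator, the CLI
  — is exactly reproducible without the thermodynamic engine. Wobble
  pairs are excluded deliberately: with them, pair maximization leaves
  almost no dangling ends on random 4-letter sequences and the phenotype
  space collapses to junk.

Fold results and strand profiles are cached by (engine identity,
sequence); the simulator and neighborhood searches revisit identical
sequences constantly and never fold one twice.

## Phenotype classification

A genotype is a strand plus its reverse complement (replication always
produces the complement). Each strand contributes three bits — 5' end,
catalytic fold, 3' end — so phenotypes coarse-grain to 64 cases, mapped
totally onto six classes: a genotype is *viable* iff both strands carry a
3' end; a strand is *replicase-like* (5' end + catalytic fold),
*staller-like* (5' end, no fold) or *inert* (no 5' end). Viable with a
replicase-like strand → unit of replication; viable without → parasite
(this subsumes viable genotypes with a staller-like strand, the broadest
reading that keeps the map total). Nonviable: replicase only → helper;
staller only → staller; one of each → hybrid; no 5' end at all → junk.
Classification is symmetric under strand swap, so a genotype and its
complement always classify identically.

## The spatial simulator

Toroidal square lattice (default 512×512; studies here run desk-scale
fields of 24–64 cells a side), at most one molecule per cell. One Monte
Carlo step visits all cells in a fresh random permutation; for an occupied
cell, in order: (1) complex formation with a uniformly chosen free Moore
neighbor — orientation drawn proportionally to (k1_xy, k1_yx), residual
mass = no complex — or, if the visited molecule presents its 5' end in a
complex, dissociation with probability k2; (2) replication: a complexed,
catalytic 5'-presenter copies its partner with probability κ (default 1)
into a uniform empty cell adjacent to either complex cell, as the mutated
reverse complement, and the complex breaks; (3) diffusion: a random-walk
step (complexes move rigidly as a unit and skip the move with probability
0.1); (4) decay with probability d = 0.03, a dying partner freeing the
survivor. Complex-level events (dissociation, replication, rigid moves)
are anchored to the 5'-presenting member so each complex is handled once
per sweep. Only substitutions are implemented (per-base probability μ,
uniform over the three alternatives); length is constant.

In the evolvable-μ mode each molecule carries its own μ; whenever a copy
acquired at least one substitution, the offspring's μ is the template's
plus a draw from U(0, ε) (ε = 5×10⁻⁴ by default) or U(−ε, ε) in the
unbiased variant, clamped to [0, 1].

Interventions run at the end of every step: `remove_class` deletes all
molecules of a target functional class; `class_to_junk` marks them inert
(they never bind again and count as junk). Observers (per-class
abundances, Hamming-distance histograms against a reference — using the
min-over-strands distance — plain-text snapshots, ancestry edges, lineage
labels for half-field competition experiments) sample at configurable
intervals. All randomness flows from one seeded generator, so runs replay
bit-identically.

## Mutational neighborhoods

`hd1_spectrum` classifies all 3ν single-substitution mutants (150 for
ν = 50); neutrality λ is the unit-of-replication fraction.
`tails_only_spectrum` restricts substitutions to the catalytic strand's
dangling ends (a modularity probe). Three searches probe larger
distances: breadth-first expansion retaining units with replication rate
at least the reference's ("core neutral"), the same without the rate
filter ("pseudo neutral"), and direct random sampling at each exact
Hamming distance. Layers above 10⁴ retained units are subsampled; the
sampler moves to the next distance after 10⁵ fruitless tries. Genotype
identity is the canonical strand (lexicographically smaller of
strand/complement); distances between genotypes use the minimum over
strand pairings.

The scalar replication rate of a genotype is
½[P(c5°c3) + P(c5°t3)] for the replicase-like strand c and opposite
strand t — the mean probability that c binds (and hence can replicate)
its own strand and the complement. Genotypes without a replicase-like
strand score 0. If both strands qualify, the better one counts.

## The replication-rate optimizer

The null model: what do replicators look like when *only* replication
rate is selected, with no ecology? An elitist GA over plus-strand
sequences (population 100, tournament 3, per-offspring mutation 0.01 per
base with at least one substitution forced, elite 1) maximizes the
replication-rate proxy under a structural constraint: *both_catalytic*
(both strands fold catalytic) or *single_catalytic* (only the plus strand
may). Fitness additionally requires viability — a genotype that cannot
itself be replicated has no replication rate to speak of — and is 0 for
infeasible genotypes. Tournaments rank by (requirements met, fitness,
soft binding quality); the last term scores the dangling ends with no
structural gates and supplies a gradient across the zero-fitness plateaus
(e.g. a both-catalytic genotype whose 5' tails are still below the
recognition threshold). Each run finishes with a steepest-ascent hill
climb over all single substitutions, repeated to a local optimum; two
independent restarts are run and the best kept. The best-fitness
trajectory is non-decreasing by elitism.

Optimized units keep long, A/U-interspersed dangling ends and a high
HD = 1 neutrality — in sharp contrast to the steep, C-tailed master
sequences that evolve in the full spatial model.

## ODE models of the replicator ecology

Two mass-action schemes abstract the grid to well-mixed dynamics, with
complexes as explicit species that fire (replicate) at rate κ·θ(N).

*Closure choices (ours; flagged).* θ(N) = max(0, 1 − N/Θ) with N the
total concentration, complexes counting twice (a complex occupies two
cells): this bounds the dynamics and makes extinction an equilibrium.
Dissociation defaults to b = 1 − a per complex, mirroring the stochastic
rule k2 = 1 − k1. Decay acts per molecule: a complex is destroyed by
decay at rate 2d and returns one surviving constituent per destruction.
Unit–unit pairs can bind in either of two orientations (both strands
carry both kinds of dangling end), while unit–parasite, unit–helper,
unit–staller and parasite–staller pairs admit only one; the
`xx_orientation_factor` parameter expresses this. In the helpers scheme,
whose printed rates are equal across pair types, they are read as
per-orientation rates (factor 2); in the stallers scheme the printed
unit–unit rate already exceeds the mixed rates and is read as a total
(factor 1). This asymmetry is load-bearing: with strictly equal
effective rates the parasite's per-complex yield (κθ − d) always exceeds
the unit's ((1 − μ)κθ − 2d), so parasites would invade and exclude the
replicators at every mutation rate and no viable branch would exist.

*Helpers scheme* (X, H, P, J + four complexes): X–X and X–H complexes
replicate X, whose offspring is faithful with probability 1 − μ and
otherwise a helper/parasite/junk with fractions λ_H, λ_P, λ_J; X–P and
H–P complexes copy the parasite without error. With parasites present,
helper production is a liability (helpers replicate parasites too) and
the persistence threshold in μ *decreases* with λ_H; without parasites it
*increases*. A stable replicator–parasite coexistence equilibrium exists
at low μ (a slow spiral; transients of order 10⁴ time units) and is lost
at higher μ.

*Stallers scheme* (X, S, P, J): X–X replicates X, P–X replicates P (whose
erroneous copies are stallers or junk; by default the unit fractions
renormalized over {S, J}), X–S and P–S complexes form but never fire —
stallers sequester. Three regimes appear as staller production λ_S
varies: at low λ_S introduced parasites overrun and extinguish the
system; above a fold-like point parasites can no longer invade and X is
stable; at high μ a large λ_S itself destroys the replicators.

Equilibria are found by long integration (LSODA, nonnegativity enforced
by evaluating the right-hand side on the clipped state) plus Newton
polishing, and continued in any parameter by pseudo-arclength
continuation with finite-difference Jacobians. Stability comes from the
state-Jacobian eigenvalues; folds are flagged at parameter turning points
with a near-zero real eigenvalue, Hopf points where a complex pair's real
part changes sign, transcritical points where the branch meets the
boundary, and homoclinic locations are *estimated* from limit-cycle
period blow-up. `persistence_threshold` measures the practically
reachable viable range by integration from a standard inoculum — the
quantity used for regime orderings, which are robust to the exact
bifurcation coordinates (those depend on the closure).

## Synthetic data and scope of the tests

There are no external datasets: every experiment runs on generated
random sequences, designed test genotypes, or simulator output. Two
designed units of replication (C-only tails scoring exactly the −0.75
recognition threshold, A/U-only stems forming the catalytic multiloop, C
spacers) make the fallback engine's genotype space non-trivial and give
the simulator a replicating founder pair. Desk-scale studies use fields
of 24–64 cells a side and tens of Monte Carlo steps, random screens of
10⁵ sequences, and neighborhood searches to HD ≤ 3 — large enough to
exercise every code path and the qualitative orderings, far below the
512×512, multi-million-step regime where the original eco-evolutionary
outcomes (travelling waves, evolved master sequences, competition
winners) emerge. Passing tests therefore certify the mechanics and the
desk-scale statistics, not the long-horizon evolutionary outcomes, which
remain stochastic properties of large fields.

## Known limitations

* Engine dependence: all genotype-space fractions (screening rates,
  neutralities, class distributions) are properties of the fold engine
  and its parameter generation, not of the sequences alone. The
  Turner-1999/d1 emulation is close to, but not identical with, the
  historical 1.x engine.
* The ODE closures (θ, b defaults, decay convention, orientation factor)
  are choices; regime orderings are robust to them, exact bifurcation
  coordinates are not.
* The fallback engine's genotype space is much sparser in catalytic
  folds than the thermodynamic one; statistics measured under it are for
  testing, not for scientific comparison.
* No insertions/deletions, no variable sequence length, no pseudoknots,
  no suboptimal folds.
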