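"""Map the single-substitution neighborhood of a unit of replication.

The neutrality lambda is the fraction of the 3*nu single-substitution
mutants that remain units of replication; the rest decompose into
parasites, helpers, stallers, junk and hybrids — the functional classes
whose balance governs the ecology around a master sequence.
"""

from rnaqs.folding import NussinovFoldEngine
from rnaqs.phenotype import genotype_of
from rnaqs.spectrum import hd1_spectrum, sample_at_hd, tails_only_spectrum

UNIT = "CCCCCUUUUUUUAACCCCUUAACCAAUUCCCCAAUUCCAAAAACCCCCCC"

engine = NussinovFoldEngine()
g = genotype_of(UNIT, engine)

sp = hd1_spectrum(g, engine)
print(f"reference ({g.func_class.value}), {sp.n_mutants} HD=1 mutants")
for fc, frac in sp.fractions.items():
    print(f"  {fc.value:9s} {frac:.3f}")
print(f"neutrality lambda = {sp.lambda_neutral:.3f}")

tails = tails_only_spectrum(g, engine)
print(f"\ntails-only neutrality (dangling ends of the catalytic strand, "
      f"{tails.n_mutants} mutants): {tails.lambda_neutral:.3f}")

res = sample_at_hd(g, [2, 3], engine, cap_found=30, cap_tries=2000, seed=0)
print("\nunits found by random sampling at larger Hamming distance:")
print(res.table[["hd", "n_found"]].to_string(index=False))
print("\n(fractions close to the HD=1 values indicate a mutationally robust")
print(" neighborhood; the evolved master sequences of the study are the")
print(" opposite: steep, with lambda an order of magnitude lower)")
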