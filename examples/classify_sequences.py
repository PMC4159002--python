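"""Classify genotypes into functional classes.

A genotype is a strand plus its reverse complement; each strand
contributes three bits (5' dangling end, catalytic fold, 3' dangling end)
and the six bits determine one of six functional classes.
"""

from rnaqs.folding import NussinovFoldEngine
from rnaqs.phenotype import genotype_of, strand_class

# a designed unit of replication (C tails, A/U stems) and two degenerate cases
SEQUENCES = {
    "designed_unit": "CCCCCUUUUUUUAACCCCUUAACCAAUUCCCCAAUUCCAAAAACCCCCCC",
    "poly_A": "A" * 50,
    "alternating": "ACGU" * 12 + "AC",
}

engine = NussinovFoldEngine()
for name, seq in SEQUENCES.items():
    g = genotype_of(seq, engine)
    bits = "".join(str(int(b)) for b in g.bits)
    print(f"{name:14s} class={g.func_class.value:8s} bits={bits} "
          f"plus={strand_class(g.plus).value} minus={strand_class(g.minus).value}")
    print(f"{'':14s} fold: {g.plus.dotbracket}")

print()
print("bits are (5' end, catalytic, 3' end) for the plus then minus strand;")
print("'unit' genotypes are replicable on both strands and carry a replicase,")
print("'parasite' genotypes are replicable but cannot replicate others.")
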