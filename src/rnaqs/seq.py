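"""Small RNA sequence utilities shared across the package."""

from __future__ import annotations

RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def check_alphabet(seq: str) -> str:
    """Validate that *seq* is over {A,C,G,U}; returns the sequence unchanged."""
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"non-RNA symbols in sequence: {sorted(bad)}")
    return seq


def reverse_complement(seq: str) -> str:
    """Watson-Crick complement (A<->U, G<->C), read back antiparallel."""
    check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("Hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def genotype_hamming(a: str, b: str) -> int:
    """Distance between genotypes: minimum over strand pairings.

    A genotype is a strand together with its reverse complement, so the
    distance between two genotypes is min(HD(a, b), HD(revcomp(a), b)).
    """
    return min(hamming(a, b), hamming(reverse_complement(a), b))


def canonical_strand(seq: str) -> str:
    """Canonical representative of a genotype: the lexicographically
    smaller of the strand and its reverse complement."""
    rc = reverse_complement(seq)
    return seq if seq <= rc else rc


def random_sequence(length: int, rng) -> str:
    """Uniform random RNA sequence from a numpy Generator."""
    return "".join("ACGU"[i] for i in rng.integers(0, 4, size=length))
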