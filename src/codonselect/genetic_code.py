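"""Universal genetic code tables used throughout the package.

The codon state space everywhere in this package is the 61 sense codons of
the universal code, ordered alphabetically (AAA, AAC, ... TTT with the three
stop codons TAA, TAG, TGA removed).  This matches the convention of codon
substitution software such as codeml, where stop codons are excluded from
the Markov state space rather than assigned rate zero.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data.CodonTable import unambiguous_dna_by_id

NUCLEOTIDES = "ACGT"

_TABLE = unambiguous_dna_by_id[1]  # the standard (universal) code

STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))

#: The 61 sense codons in alphabetical order; index into this list is the
#: codon state used by the rate matrix and likelihood machinery.
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in _TABLE.forward_table if "U" not in c)
)

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

N_CODONS = len(SENSE_CODONS)  # 61

#: codon -> one-letter amino acid, sense codons only
AMINO_ACID: dict[str, str] = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a<->b is a transition."""
    return (a in _PURINES and b in _PURINES) or (
        a in _PYRIMIDINES and b in _PYRIMIDINES
    )


def translate(codon: str) -> str:
    """One-letter amino acid for a sense codon ('*' for stops)."""
    if codon in AMINO_ACID:
        return AMINO_ACID[codon]
    if codon in STOP_CODONS:
        return "*"
    raise KeyError(f"not an unambiguous codon: {codon!r}")


@lru_cache(maxsize=1)
def fourfold_families() -> frozenset[str]:
    """Two-nucleotide codon prefixes whose four completions are synonymous.

    Derived from the code itself rather than hard-coded: a prefix XY belongs
    to a fourfold-degenerate family iff XYA, XYC, XYG, XYT are all sense
    codons translating to one amino acid.  Under the universal code this
    yields exactly 8 families (Leu-CTN, Val-GTN, Ser-TCN, Pro-CCN, Thr-ACN,
    Ala-GCN, Arg-CGN, Gly-GGN).
    """
    fams = set()
    for x in NUCLEOTIDES:
        for y in NUCLEOTIDES:
            codons = [x + y + z for z in NUCLEOTIDES]
            if all(c in AMINO_ACID for c in codons):
                aas = {AMINO_ACID[c] for c in codons}
                if len(aas) == 1:
                    fams.add(x + y)
    return frozenset(fams)


@lru_cache(maxsize=1)
def single_step_changes() -> list[tuple[int, int, bool, bool]]:
    """All ordered sense-codon pairs one nucleotide apart.

    Returns tuples ``(i, j, transition, synonymous)`` with i, j codon state
    indices.  Multi-nucleotide changes are absent by construction (they get
    rate zero in the substitution model).
    """
    out = []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            a, b = diffs[0]
            out.append((i, j, is_transition(a, b), AMINO_ACID[ci] == AMINO_ACID[cj]))
    return out
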