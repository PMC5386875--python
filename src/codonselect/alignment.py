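"""Codon alignment containers, FASTA I/O, filters and fourfold-site extraction.

The pipeline consumes per-ortholog in-frame codon alignments (gap-containing
FASTA, pre-trimmed).  This module validates them (frame, alphabet, internal
stop codons), applies the length filter used for the ortholog set (keep
strictly >150 nt), extracts fourfold-degenerate third positions for
neutral-site concatenation, and builds "supergene" concatenations.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import AMINO_ACID, STOP_CODONS, fourfold_families

VALID_CHARS = frozenset("ACGTN-")

__all__ = [
    "CodonAlignment",
    "NucleotideAlignment",
    "AlignmentError",
    "read_codon_alignment",
    "write_fasta",
    "filter_min_length",
    "extract_fourfold_sites",
    "concatenate",
    "concatenate_nucleotide",
]


class AlignmentError(ValueError):
    """Raised for malformed codon alignments (frame, alphabet, stops)."""


@dataclass
class CodonAlignment:
    """In-frame aligned codon sequences for one ortholog.

    ``sequences[i]`` belongs to ``taxa[i]``; all sequences have equal length
    divisible by three, alphabet ``ACGTN-``, and no in-frame stop codon in
    any fully ungapped codon.
    """

    taxa: list[str]
    sequences: list[str]
    gene_id: str = ""

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise AlignmentError(
                f"{self.gene_id}: {len(self.taxa)} taxa vs "
                f"{len(self.sequences)} sequences"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError(f"{self.gene_id}: duplicate taxon names")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"{self.gene_id}: ragged sequence lengths {lengths}")
        (L,) = lengths or {0}
        if L % 3:
            raise AlignmentError(
                f"{self.gene_id}: alignment length {L} not divisible by 3"
            )
        for taxon, seq in zip(self.taxa, self.sequences):
            bad = set(seq) - VALID_CHARS
            if bad:
                raise AlignmentError(
                    f"{self.gene_id}/{taxon}: invalid characters {sorted(bad)}"
                )
            for k in range(0, L, 3):
                codon = seq[k : k + 3]
                if codon in STOP_CODONS:
                    raise AlignmentError(
                        f"{self.gene_id}/{taxon}: internal stop codon "
                        f"{codon} at codon index {k // 3}"
                    )

    @property
    def n_nt(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_codons(self) -> int:
        return self.n_nt // 3

    def codon(self, taxon_idx: int, codon_idx: int) -> str:
        return self.sequences[taxon_idx][3 * codon_idx : 3 * codon_idx + 3]

    def subset_taxa(self, taxa) -> "CodonAlignment":
        """Restrict to (and reorder by) the given taxa."""
        idx = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in idx]
        if missing:
            raise AlignmentError(f"{self.gene_id}: taxa not present: {missing}")
        return CodonAlignment(
            taxa=list(taxa),
            sequences=[self.sequences[idx[t]] for t in taxa],
            gene_id=self.gene_id,
        )


@dataclass
class NucleotideAlignment:
    """Equal-length nucleotide strings with per-column provenance.

    ``source_map[j] = (gene_id, codon_index)`` records the codon column each
    alignment column came from (fourfold-site extraction keeps one column —
    the third position — per emitted codon column).
    """

    taxa: list[str]
    sequences: list[str]
    source_map: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged nucleotide alignment lengths {lengths}")

    @property
    def n_nt(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


def read_codon_alignment(path, gene_id: str | None = None) -> CodonAlignment:
    """Read one FASTA codon alignment; taxa keep file order.

    Lowercase input is accepted and normalised to uppercase.  Raises
    :class:`AlignmentError` naming the gene, taxon and codon index for
    in-frame stop codons, and for ragged or out-of-frame input.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no FASTA records")
    if gene_id is None:
        gene_id = os.path.splitext(os.path.basename(str(path)))[0]
    return CodonAlignment(
        taxa=[r.id for r in records],
        sequences=[str(r.seq).upper() for r in records],
        gene_id=gene_id,
    )


def write_fasta(aln: CodonAlignment | NucleotideAlignment, path) -> None:
    """Write an alignment as wrapped FASTA (60 columns, Biopython default)."""
    records = [
        SeqRecord(Seq(s), id=t, description="")
        for t, s in zip(aln.taxa, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def filter_min_length(aln: CodonAlignment, min_nt: int = 150) -> bool:
    """Keep rule for trimmed alignments: strictly more than ``min_nt`` sites.

    Returns True (keep) iff the alignment is longer than ``min_nt``
    nucleotides; a 150-nt alignment is dropped under the default.
    """
    return aln.n_nt > min_nt


def extract_fourfold_sites(aln: CodonAlignment) -> NucleotideAlignment:
    """Third positions of codon columns conserved within a fourfold family.

    A codon column qualifies when every taxon's codon is ungapped and
    unambiguous and all taxa share the identical two-nucleotide prefix
    belonging to one of the 8 fourfold-degenerate families — the strict
    reading of "fourfold sites of conserved amino acids" under which every
    third-position change is guaranteed synonymous.  Columns with any gap or
    ``N`` are excluded rather than imputed.
    """
    fams = fourfold_families()
    cols: list[int] = []
    for k in range(aln.n_codons):
        codons = [s[3 * k : 3 * k + 3] for s in aln.sequences]
        if any(c not in AMINO_ACID for c in codons):
            continue  # gap, N, or (impossible here) stop
        prefixes = {c[:2] for c in codons}
        if len(prefixes) == 1 and codons[0][:2] in fams:
            cols.append(k)
    return NucleotideAlignment(
        taxa=list(aln.taxa),
        sequences=["".join(s[3 * k + 2] for k in cols) for s in aln.sequences],
        source_map=[(aln.gene_id, k) for k in cols],
    )


def _check_taxon_sets(alignments) -> list[str]:
    if not alignments:
        raise AlignmentError("nothing to concatenate")
    ref = alignments[0].taxa
    for a in alignments[1:]:
        if set(a.taxa) != set(ref):
            raise AlignmentError(
                "taxon-set mismatch in concatenation: "
                f"{sorted(set(a.taxa) ^ set(ref))}"
            )
    return list(ref)


def concatenate(alignments, gene_id: str = "supergene") -> CodonAlignment:
    """Concatenate codon alignments sharing a taxon set into a supergene.

    Taxon order follows the first input; inputs are concatenated in the
    given order.  The result carries a ``source_map`` attribute listing
    ``(gene_id, codon_index)`` per codon column.
    """
    taxa = _check_taxon_sets(alignments)
    parts = {t: [] for t in taxa}
    source = []
    for a in alignments:
        sub = a.subset_taxa(taxa)
        for t, s in zip(sub.taxa, sub.sequences):
            parts[t].append(s)
        source.extend((a.gene_id, k) for k in range(a.n_codons))
    out = CodonAlignment(
        taxa=taxa, sequences=["".join(parts[t]) for t in taxa], gene_id=gene_id
    )
    out.source_map = source  # type: ignore[attr-defined]
    return out


def concatenate_nucleotide(blocks) -> NucleotideAlignment:
    """Concatenate nucleotide blocks (e.g. per-gene fourfold sites)."""
    taxa = _check_taxon_sets(blocks)
    parts = {t: [] for t in taxa}
    source = []
    for b in blocks:
        order = {t: i for i, t in enumerate(b.taxa)}
        for t in taxa:
            parts[t].append(b.sequences[order[t]])
        source.extend(b.source_map or [("", j) for j in range(b.n_nt)])
    return NucleotideAlignment(
        taxa=taxa,
        sequences=["".join(parts[t]) for t in taxa],
        source_map=source,
    )
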