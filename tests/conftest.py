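import numpy as np
import pytest

from codonselect.genetic_code import SENSE_CODONS
from codonselect.alignment import CodonAlignment
from codonselect.trees import HIGHLAND, LOWLAND, make_study_tree

BRANCH_SITE_TAXA = [*HIGHLAND, *LOWLAND]

#: per-branch omega of the study conditions (elevated Schizothoracine clade)
STUDY_OMEGA = {
    **{b: 0.3 for b in ("G_dobula", "P_kaznakovi", "S_gongshanensis",
                        "S_prenanti", "A", "B", "C")},
    **{b: 0.16 for b in ("C_idella", "D_rerio")},
}


@pytest.fixture
def study_tree():
    return make_study_tree()


@pytest.fixture
def branch_site_tree(study_tree):
    """Four-taxon tree with the highland tips tagged as foreground."""
    tree = study_tree.copy().set_foreground(HIGHLAND)
    return tree.prune_to(BRANCH_SITE_TAXA)


def make_alignment(codon_rows, taxa=None, gene_id="toy"):
    """Alignment from per-taxon codon lists, e.g. [["CTT","ATG"], ...]."""
    taxa = taxa or [f"T{i+1}" for i in range(len(codon_rows))]
    return CodonAlignment(
        taxa=list(taxa),
        sequences=["".join(r) for r in codon_rows],
        gene_id=gene_id,
    )


def random_codons(rng, n):
    return [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n)]
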