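import numpy as np
import pytest

from glypred.sequence_io import PeptideWindow, ProteinRecord, SiteAnnotation, extract_window

ALPHABET = "ACDEFGHIKLMNPQRSTVWYO"


def make_window(peptide: str, label: int = 1, pid: str = "p", pos: int = 12) -> PeptideWindow:
    """Wrap a literal peptide string in a PeptideWindow for encoder tests."""
    flank = len(peptide) // 2
    return PeptideWindow(
        peptide=peptide,
        center_residue=peptide[flank],
        source=SiteAnnotation(pid, pos, label),
        pad_count=peptide.count("O"),
    )


def random_window(rng: np.random.Generator, width: int = 23) -> PeptideWindow:
    """A seeded random window over the full 21-letter alphabet."""
    return make_window("".join(rng.choice(list(ALPHABET), size=width)))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_protein():
    return ProteinRecord("p1", "ACDEFGHIKLMNPQRSTVWY")


@pytest.fixture
def fasta_file(tmp_path):
    path = tmp_path / "toy.fasta"
    path.write_text(">p1\nMKVLAKWTTK\n>p2\nAAAK\nKCDE\n")
    return path


@pytest.fixture
def annotation_file(tmp_path):
    path = tmp_path / "sites.tsv"
    path.write_text(
        "protein_id\tposition\tlabel\n"
        "p1\t2\t1\n"
        "p1\t6\t-1\n"
        "p2\t4\t1\n"
    )
    return path
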