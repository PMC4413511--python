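"""FASTA / site-annotation input and fixed-width peptide window extraction.

Windows are ``2*flank + 1`` residues wide, centered on the annotated
residue; positions falling outside the protein are filled with the
padding letter ``O``. Coordinates are 1-based and inclusive throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
PAD = "O"

#: Ambiguity / non-standard codes remapped to the padding letter in
#: permissive mode.
NONSTANDARD_AA = set("BJUXZ")


class SequenceError(ValueError):
    """Malformed sequence or annotation input."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceError(f"protein {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteAnnotation:
    """A candidate site: protein, 1-based residue position, class label."""

    protein_id: str
    position: int
    label: int  # +1 = modified site, -1 = non-site

    def __post_init__(self) -> None:
        if self.position < 1:
            raise SequenceError(
                f"annotation {self.protein_id!r}: position must be >= 1, got {self.position}"
            )
        if self.label not in (+1, -1):
            raise SequenceError(
                f"annotation {self.protein_id!r}: label must be +1 or -1, got {self.label}"
            )


@dataclass(frozen=True)
class PeptideWindow:
    """Fixed-width peptide around a site, O-padded at sequence ends."""

    peptide: str
    center_residue: str
    source: SiteAnnotation
    pad_count: int

    @property
    def label(self) -> int:
        return self.source.label


_LABEL_TOKENS = {
    "1": +1, "+1": +1, "pos": +1, "positive": +1, "true": +1,
    "-1": -1, "0": -1, "neg": -1, "negative": -1, "false": -1,
}


def _clean_sequence(raw: str, protein_id: str, strict: bool) -> str:
    seq = "".join(raw.split()).upper()
    cleaned = []
    for ch in seq:
        if ch in STANDARD_AA:
            cleaned.append(ch)
        elif strict:
            raise SequenceError(
                f"protein {protein_id!r}: disallowed character {ch!r} in strict mode"
            )
        elif ch in NONSTANDARD_AA or ch == PAD:
            cleaned.append(PAD)
        else:
            raise SequenceError(f"protein {protein_id!r}: unrecognized character {ch!r}")
    return "".join(cleaned)


def read_fasta(path: str | Path, strict: bool = True) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased and whitespace-stripped; entry order is
    preserved. In strict mode (default) any character outside the 20
    standard one-letter codes raises :class:`SequenceError`; in
    permissive mode the ambiguity codes B, J, U, X, Z are mapped to the
    padding letter ``O``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = [
        ProteinRecord(id=rec.id, sequence=_clean_sequence(str(rec.seq), rec.id, strict))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    return records


def read_annotations(path: str | Path, delimiter: str = "\t") -> list[SiteAnnotation]:
    """Read site annotations from delimited text.

    Expected columns: protein_id, position (1-based), label. A header
    line (one whose position column is not an integer and whose label
    token is unknown) is skipped. Labels are normalized to {+1, -1}.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    annotations: list[SiteAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) < 3:
                raise SequenceError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            pid, pos_s, label_s = parts[0].strip(), parts[1].strip(), parts[2].strip()
            if lineno == 1 and not _is_int(pos_s):
                continue  # header
            if not _is_int(pos_s):
                raise SequenceError(f"{path}:{lineno}: non-integer position {pos_s!r}")
            token = label_s.lower()
            if token not in _LABEL_TOKENS:
                raise SequenceError(f"{path}:{lineno}: unknown label token {label_s!r}")
            annotations.append(SiteAnnotation(pid, int(pos_s), _LABEL_TOKENS[token]))
    return annotations


def _is_int(s: str) -> bool:
    try:
        int(s)
    except ValueError:
        return False
    return True


def extract_window(
    protein: ProteinRecord,
    position: int,
    flank: int = 11,
    annotation: SiteAnnotation | None = None,
) -> PeptideWindow:
    """Extract the ``2*flank + 1`` window centered at ``position`` (1-based).

    Positions outside the protein are filled with ``O``; the number of
    padding letters is recorded in ``pad_count``.
    """
    seq = protein.sequence
    n = len(seq)
    if not 1 <= position <= n:
        raise SequenceError(
            f"protein {protein.id!r}: position {position} out of range 1..{n}"
        )
    lo = position - 1 - flank  # 0-based, may be negative
    hi = position - 1 + flank  # inclusive
    left_pad = max(0, -lo)
    right_pad = max(0, hi - (n - 1))
    core = seq[max(0, lo): min(n, hi + 1)]
    peptide = PAD * left_pad + core + PAD * right_pad
    source = annotation or SiteAnnotation(protein.id, position, -1)
    return PeptideWindow(
        peptide=peptide,
        center_residue=seq[position - 1],
        source=source,
        pad_count=left_pad + right_pad,
    )


def build_dataset(
    proteins: Iterable[ProteinRecord],
    annotations: Sequence[SiteAnnotation],
    max_pad: int | None = None,
    flank: int = 11,
    require_center: str | None = "K",
    strict_center: bool = False,
) -> list[PeptideWindow]:
    """Extract one window per annotation, optionally dropping heavily padded ones.

    ``require_center`` guards the expected center residue (lysine by
    default): mismatches warn, or raise when ``strict_center`` is set.
    Pass ``require_center=None`` to disable the check. Windows with
    ``pad_count > max_pad`` are dropped when ``max_pad`` is given.
    """
    by_id = {p.id: p for p in proteins}
    kept: list[PeptideWindow] = []
    dropped = {+1: 0, -1: 0}
    for ann in annotations:
        if ann.protein_id not in by_id:
            raise SequenceError(f"annotation references unknown protein {ann.protein_id!r}")
        window = extract_window(by_id[ann.protein_id], ann.position, flank, annotation=ann)
        if require_center and window.center_residue != require_center:
            msg = (
                f"protein {ann.protein_id!r} position {ann.position}: center residue is "
                f"{window.center_residue!r}, expected {require_center!r}"
            )
            if strict_center:
                raise SequenceError(msg)
            warnings.warn(msg, stacklevel=2)
        if max_pad is not None and window.pad_count > max_pad:
            dropped[ann.label] += 1
            continue
        kept.append(window)
    if max_pad is not None:
        n_pos = sum(1 for w in kept if w.label == +1)
        n_neg = len(kept) - n_pos
        warnings.warn(
            f"max_pad={max_pad}: kept {n_pos}+/{n_neg}- windows, "
            f"dropped {dropped[+1]}+/{dropped[-1]}-",
            stacklevel=2,
        )
    return kept


def write_windows(windows: Sequence[PeptideWindow], path: str | Path) -> None:
    """Write windows as TSV: id, position, label, peptide, pad_count."""
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tlabel\tpeptide\tpad_count\n")
        for w in windows:
            fh.write(
                f"{w.source.protein_id}\t{w.source.position}\t{w.label}\t"
                f"{w.peptide}\t{w.pad_count}\n"
            )


def read_windows(path: str | Path) -> list[PeptideWindow]:
    """Read windows written by :func:`write_windows`."""
    windows: list[PeptideWindow] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("protein_id"):
            raise SequenceError(f"{path}: missing window header line")
        for line in fh:
            pid, pos_s, label_s, peptide, pad_s = line.rstrip("\n").split("\t")
            ann = SiteAnnotation(pid, int(pos_s), int(label_s))
            flank = len(peptide) // 2
            windows.append(
                PeptideWindow(
                    peptide=peptide,
                    center_residue=peptide[flank],
                    source=ann,
                    pad_count=int(pad_s),
                )
            )
    return windows
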