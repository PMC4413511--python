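"""Seeded synthetic proteins and site annotations with planted signal.

Proteins are drawn from a background letter distribution; candidate
sites are lysines placed far enough apart that their 23-residue windows
never overlap. Positive sites optionally receive planted k-spaced
residue pairs (each with its own enrichment probability) and/or a tilt
of the residue distribution at one window site toward a chosen
physicochemical factor. Negatives see the background only, so only the
planted signal separates the classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from glypred.atchley import ATCHLEY_FACTORS
from glypred.sequence_io import STANDARD_AA, ProteinRecord, SiteAnnotation

_FLANK = 11
_WINDOW = 2 * _FLANK + 1


@dataclass(frozen=True)
class PlantedPair:
    """An ordered residue pair planted at spacing k with probability pi."""

    a: str
    b: str
    k: int
    pi: float

    def __post_init__(self) -> None:
        if self.a not in STANDARD_AA or self.b not in STANDARD_AA:
            raise ValueError(f"planted letters must be standard residues: {self.a}, {self.b}")
        if not 1 <= self.k <= _WINDOW - 2:
            raise ValueError(f"spacing k={self.k} does not fit a {_WINDOW}-mer window")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError(f"enrichment probability must be in [0, 1], got {self.pi}")


@dataclass(frozen=True)
class FactorShift:
    """Tilt the site's residue distribution by exp(delta * factor score)."""

    site: int  # 1..23, window coordinates (12 = center)
    factor: int  # 1..5
    delta: float

    def __post_init__(self) -> None:
        if not 1 <= self.site <= _WINDOW or self.site == _FLANK + 1:
            raise ValueError(f"site must be in 1..{_WINDOW} and not the center")
        if not 1 <= self.factor <= 5:
            raise ValueError(f"factor must be in 1..5, got {self.factor}")


@dataclass(frozen=True)
class FixtureSpec:
    n_pos: int = 89
    n_neg: int = 126
    protein_length: int = 200
    planted_pairs: tuple[PlantedPair, ...] = ()
    factor_shift: FactorShift | None = None
    background: tuple[float, ...] = field(default_factory=lambda: (1 / 20,) * 20)
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        if len(self.background) != 20 or not np.isclose(sum(self.background), 1.0):
            raise ValueError("background must be a 20-letter probability vector")
        if self.protein_length < _WINDOW + 2:
            raise ValueError(f"protein_length must be >= {_WINDOW + 2}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "protein_length": self.protein_length,
            "planted_pairs": [
                [p.a, p.b, p.k, p.pi] for p in self.planted_pairs
            ],
            "factor_shift": (
                [self.factor_shift.site, self.factor_shift.factor, self.factor_shift.delta]
                if self.factor_shift
                else None
            ),
            "background": list(self.background),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureSpec":
        payload = json.loads(Path(path).read_text())
        return cls(
            n_pos=payload["n_pos"],
            n_neg=payload["n_neg"],
            protein_length=payload["protein_length"],
            planted_pairs=tuple(PlantedPair(*p) for p in payload["planted_pairs"]),
            factor_shift=(
                FactorShift(*payload["factor_shift"]) if payload["factor_shift"] else None
            ),
            background=tuple(payload["background"]),
            seed=payload["seed"],
        )


def _pair_offsets(pairs: Sequence[PlantedPair]) -> list[tuple[int, int]]:
    """Deterministic non-overlapping window offsets for each planted pair.

    Offsets are relative to the center (0 = the lysine, excluded). The
    first letter goes as close to the center as available space allows.
    """
    taken = {0}
    placements: list[tuple[int, int]] = []
    for pair in pairs:
        placed = False
        for d in list(range(1, _FLANK + 1)) + list(range(-1, -_FLANK - 1, -1)):
            d2 = d + pair.k + 1
            if abs(d2) > _FLANK:
                continue
            if d in taken or d2 in taken:
                continue
            taken.update((d, d2))
            placements.append((d, d2))
            placed = True
            break
        if not placed:
            raise ValueError(f"cannot place planted pair {pair} inside the window")
    return placements


def generate(spec: FixtureSpec) -> tuple[list[ProteinRecord], list[SiteAnnotation]]:
    """Generate proteins and annotations; fully reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    letters = np.array(list(STANDARD_AA))
    bg = np.asarray(spec.background)
    placements = _pair_offsets(spec.planted_pairs)

    # non-overlapping candidate centers, windows fully interior
    step = _WINDOW + 1
    first = _FLANK + 2
    centers = list(range(first, spec.protein_length - _FLANK, step))
    if not centers:
        raise ValueError("protein_length too short for any interior site")

    n_total = spec.n_pos + spec.n_neg
    n_proteins = -(-n_total // len(centers))

    shift_probs = None
    if spec.factor_shift is not None:
        scores = np.array(
            [ATCHLEY_FACTORS[a][spec.factor_shift.factor - 1] for a in STANDARD_AA]
        )
        w = bg * np.exp(spec.factor_shift.delta * scores)
        shift_probs = w / w.sum()

    labels = [+1] * spec.n_pos + [-1] * spec.n_neg
    proteins: list[ProteinRecord] = []
    annotations: list[SiteAnnotation] = []
    site_cursor = 0
    for p in range(n_proteins):
        seq = rng.choice(letters, size=spec.protein_length, p=bg)
        pid = f"synth{p + 1:03d}"
        for center in centers:
            if site_cursor >= n_total:
                break
            label = labels[site_cursor]
            c0 = center - 1  # 0-based
            seq[c0] = "K"
            if label == +1:
                for pair, (d, d2) in zip(spec.planted_pairs, placements):
                    if rng.random() < pair.pi:
                        seq[c0 + d] = pair.a
                        seq[c0 + d2] = pair.b
                if shift_probs is not None:
                    off = spec.factor_shift.site - (_FLANK + 1)
                    seq[c0 + off] = rng.choice(letters, p=shift_probs)
            annotations.append(SiteAnnotation(pid, center, label))
            site_cursor += 1
        proteins.append(ProteinRecord(pid, "".join(seq)))
    return proteins, annotations


def write_fixture(
    spec: FixtureSpec, fasta_path: str | Path, annotation_path: str | Path
) -> tuple[list[ProteinRecord], list[SiteAnnotation]]:
    """Generate and write FASTA + annotation TSV; byte-identical per seed."""
    proteins, annotations = generate(spec)
    with open(fasta_path, "w") as fh:
        for rec in proteins:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i: i + 60] + "\n")
    with open(annotation_path, "w") as fh:
        fh.write("protein_id\tposition\tlabel\n")
        for ann in annotations:
            fh.write(f"{ann.protein_id}\t{ann.position}\t{ann.label}\n")
    return proteins, annotations
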