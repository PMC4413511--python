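"""Canonical 1900-dimensional encoding of 23-residue peptide windows.

Layout (1-based feature indices, window size ``W`` = 23, ``kmax`` = 4):

===========  ==========  =====================================================
indices      block       order
===========  ==========  =====================================================
1..21        frequency   alphabet order, padding letter ``O`` last
22..136      factor      grouped by site: ``21 + 5*(site-1) + factor``
137..1900    cksaap      blocks by increasing spacing ``k`` = 1..4; within a
                         block ordered pairs row-major over the alphabet:
                         ``136 + 441*(k-1) + 21*(rank(a)-1) + rank(b)``
===========  ==========  =====================================================

CKSAAP counts the ordered pairs ``window[p] == a and window[p+k+1] == b``
(exactly ``k`` intervening residues); by default counts are normalized by
the number of available positions, ``W - k - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from glypred.atchley import ATCHLEY_FACTORS, factor_matrix
from glypred.sequence_io import PeptideWindow

#: 20 standard residues in one-letter alphabetical order, padding letter last.
ALPHABET = "ACDEFGHIKLMNPQRSTVWYO"
N_LETTERS = len(ALPHABET)  # 21
N_PAIRS = N_LETTERS * N_LETTERS  # 441
N_FACTORS = 5

_RANK = {a: i + 1 for i, a in enumerate(ALPHABET)}  # 1-based
_CODE = {a: i for i, a in enumerate(ALPHABET)}  # 0-based


class FeatureError(ValueError):
    """Invalid feature parameters or index."""


@dataclass(frozen=True)
class FeatureDescriptor:
    """One feature of the canonical vector, addressable by index or name."""

    index: int
    block: str  # "frequency" | "factor" | "cksaap"
    name: str
    letter: str | None = None  # frequency block
    site: int | None = None  # factor block, 1..W
    factor: int | None = None  # factor block, 1..5
    a: str | None = None  # cksaap first letter
    b: str | None = None  # cksaap second letter
    k: int | None = None  # cksaap spacing


def feature_index(
    block: str,
    *,
    letter: str | None = None,
    site: int | None = None,
    factor: int | None = None,
    a: str | None = None,
    b: str | None = None,
    k: int | None = None,
    window_size: int = 23,
    kmax: int = 4,
) -> int:
    """Map feature parameters to the canonical 1-based index."""
    n_freq = N_LETTERS
    n_factor = N_FACTORS * window_size
    if block == "frequency":
        if letter not in _RANK:
            raise FeatureError(f"unknown letter {letter!r}")
        return _RANK[letter]
    if block == "factor":
        if site is None or not 1 <= site <= window_size:
            raise FeatureError(f"site must be in 1..{window_size}, got {site}")
        if factor is None or not 1 <= factor <= N_FACTORS:
            raise FeatureError(f"factor must be in 1..{N_FACTORS}, got {factor}")
        return n_freq + N_FACTORS * (site - 1) + factor
    if block == "cksaap":
        if a not in _RANK or b not in _RANK:
            raise FeatureError(f"unknown pair letters ({a!r}, {b!r})")
        if k is None or not 1 <= k <= kmax:
            raise FeatureError(f"spacing k must be in 1..{kmax}, got {k}")
        return n_freq + n_factor + N_PAIRS * (k - 1) + N_LETTERS * (_RANK[a] - 1) + _RANK[b]
    raise FeatureError(f"unknown block {block!r}")


def feature_name(index: int, window_size: int = 23, kmax: int = 4) -> FeatureDescriptor:
    """Inverse of :func:`feature_index`; round-trips exactly."""
    n_freq = N_LETTERS
    n_factor = N_FACTORS * window_size
    total = n_freq + n_factor + N_PAIRS * kmax
    if not 1 <= index <= total:
        raise FeatureError(f"index must be in 1..{total}, got {index}")
    if index <= n_freq:
        letter = ALPHABET[index - 1]
        return FeatureDescriptor(index, "frequency", f"freq_{letter}", letter=letter)
    if index <= n_freq + n_factor:
        off = index - n_freq - 1
        site, factor = off // N_FACTORS + 1, off % N_FACTORS + 1
        return FeatureDescriptor(
            index, "factor", f"F{factor}_site{site}", site=site, factor=factor
        )
    off = index - n_freq - n_factor - 1
    k = off // N_PAIRS + 1
    pair = off % N_PAIRS
    a, b = ALPHABET[pair // N_LETTERS], ALPHABET[pair % N_LETTERS]
    return FeatureDescriptor(index, "cksaap", f"{a}{'^' * k}{b}", a=a, b=b, k=k)


def parse_feature_name(name: str, window_size: int = 23, kmax: int = 4) -> FeatureDescriptor:
    """Parse a canonical feature name back to its descriptor."""
    if name.startswith("freq_") and len(name) == 6:
        return feature_name(feature_index("frequency", letter=name[5]), window_size, kmax)
    if name.startswith("F") and "_site" in name:
        f_s, site_s = name[1:].split("_site")
        idx = feature_index(
            "factor", site=int(site_s), factor=int(f_s), window_size=window_size
        )
        return feature_name(idx, window_size, kmax)
    if len(name) >= 3 and name[0] in _RANK and name[-1] in _RANK and set(name[1:-1]) == {"^"}:
        idx = feature_index(
            "cksaap", a=name[0], b=name[-1], k=len(name) - 2,
            window_size=window_size, kmax=kmax,
        )
        return feature_name(idx, window_size, kmax)
    raise FeatureError(f"unparseable feature name {name!r}")


class FeatureSpace:
    """The ordered list of feature descriptors for a window size and kmax."""

    def __init__(self, window_size: int = 23, kmax: int = 4):
        if not 1 <= kmax <= N_LETTERS:
            raise FeatureError(f"kmax must be in 1..{N_LETTERS}, got {kmax}")
        self.window_size = window_size
        self.kmax = kmax
        self.n_features = N_LETTERS + N_FACTORS * window_size + N_PAIRS * kmax
        self.descriptors = [
            feature_name(i, window_size, kmax) for i in range(1, self.n_features + 1)
        ]
        self.names = [d.name for d in self.descriptors]

    def __len__(self) -> int:
        return self.n_features

    def __getitem__(self, index: int) -> FeatureDescriptor:
        return feature_name(index, self.window_size, self.kmax)

    def index_of(self, name: str) -> int:
        return parse_feature_name(name, self.window_size, self.kmax).index


@dataclass
class FeatureMatrix:
    """Samples x features table with labels and canonical feature names."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise FeatureError("values must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise FeatureError(
                f"{self.values.shape[1]} columns vs {len(self.feature_names)} names"
            )
        if self.values.shape[0] != len(self.labels):
            raise FeatureError("row count != label count")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(self.values.shape[0])]
        if np.isnan(self.values).any():
            raise FeatureError("feature matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, indices_1based: Sequence[int]) -> "FeatureMatrix":
        """Restrict columns to the given canonical (1-based) feature indices."""
        cols = [i - 1 for i in indices_1based]
        return FeatureMatrix(
            self.values[:, cols],
            [self.feature_names[c] for c in cols],
            self.labels,
            list(self.sample_ids),
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV with header of feature names; bit-exact round trip."""
        with open(path, "w") as fh:
            fh.write("sample_id\tlabel\t" + "\t".join(self.feature_names) + "\n")
            for sid, lab, row in zip(self.sample_ids, self.labels, self.values):
                fh.write(f"{sid}\t{lab}\t" + "\t".join("%.17g" % v for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["sample_id", "label"]:
                raise FeatureError(f"{path}: expected 'sample_id' and 'label' columns")
            names = header[2:]
            ids, labels, rows = [], [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                ids.append(parts[0])
                labels.append(int(parts[1]))
                rows.append([float(v) for v in parts[2:]])
        return cls(np.array(rows, dtype=float), names, np.array(labels), ids)


def _encode_windows(peptides: Sequence[str]) -> np.ndarray:
    """Letter-code matrix (n, W) of int8 alphabet codes."""
    try:
        return np.array(
            [[_CODE[ch] for ch in pep] for pep in peptides], dtype=np.int8
        )
    except KeyError as exc:
        raise FeatureError(f"peptide contains letter outside alphabet: {exc}") from exc


def encode_frequency(window: PeptideWindow) -> np.ndarray:
    """Per-letter occurrence frequency over the 21-letter alphabet (sums to 1)."""
    codes = _encode_windows([window.peptide])[0]
    counts = np.bincount(codes, minlength=N_LETTERS).astype(float)
    return counts / len(window.peptide)


def encode_factors(window: PeptideWindow, table: dict | None = None) -> np.ndarray:
    """Five factor scores per site, grouped by site (site 1 first). O scores 0."""
    scores = (
        factor_matrix(ALPHABET)
        if table is None
        else np.array([table[a] for a in ALPHABET], dtype=float)
    )
    codes = _encode_windows([window.peptide])[0]
    return scores[codes].ravel()


def encode_cksaap(
    window: PeptideWindow, kmax: int = 4, normalize: bool = True
) -> np.ndarray:
    """k-spaced pair counts for k = 1..kmax, 441 ordered pairs per block."""
    if not 1 <= kmax <= N_LETTERS:
        raise FeatureError(f"kmax must be in 1..{N_LETTERS}, got {kmax}")
    return _cksaap_block(_encode_windows([window.peptide]), kmax, normalize)[0]


def _cksaap_block(codes: np.ndarray, kmax: int, normalize: bool) -> np.ndarray:
    n, width = codes.shape
    blocks = []
    for k in range(1, kmax + 1):
        n_pos = width - k - 1
        if n_pos <= 0:
            raise FeatureError(f"spacing k={k} does not fit window of width {width}")
        pair_idx = codes[:, :n_pos].astype(np.int32) * N_LETTERS + codes[:, k + 1:]
        flat = (np.arange(n)[:, None] * N_PAIRS + pair_idx).ravel()
        counts = np.bincount(flat, minlength=n * N_PAIRS).reshape(n, N_PAIRS).astype(float)
        blocks.append(counts / n_pos if normalize else counts)
    return np.hstack(blocks)


def encode_all(
    windows: Sequence[PeptideWindow], kmax: int = 4, normalize: bool = True
) -> FeatureMatrix:
    """Encode windows into the canonical [frequency | factor | cksaap] matrix."""
    if not windows:
        raise FeatureError("no windows to encode")
    widths = {len(w.peptide) for w in windows}
    if len(widths) != 1:
        raise FeatureError(f"windows have mixed widths {sorted(widths)}")
    width = widths.pop()
    codes = _encode_windows([w.peptide for w in windows])
    n = len(windows)

    freq = np.apply_along_axis(
        lambda c: np.bincount(c, minlength=N_LETTERS), 1, codes
    ).astype(float) / width
    factors = factor_matrix(ALPHABET)[codes].reshape(n, width * N_FACTORS)
    cksaap = _cksaap_block(codes, kmax, normalize)

    space = FeatureSpace(window_size=width, kmax=kmax)
    labels = np.array([w.label for w in windows])
    ids = [f"{w.source.protein_id}:{w.source.position}" for w in windows]
    return FeatureMatrix(np.hstack([freq, factors, cksaap]), space.names, labels, ids)
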