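"""Numeric feature encodings for peptide windows.

Three encoders are provided, all operating over the fixed 21-letter
alphabet ``ACDEFGHIKLMNPQRSTVWYX`` (20 amino acids + the padding dummy X):

one-hot
    Per-position 21-dimensional indicator vectors; a 17-mer becomes a
    17 x 21 = 357-dimensional vector.

AAindex
    Per-position lookup of nine physicochemical property scales
    (hydrophilicity, mean polarity, isoelectric point, refractivity,
    average flexibility, buried-residue volume, electron-ion interaction
    potential, transfer free energy to surface, consensus normalized
    hydrophobicity); a 17-mer becomes a 17 x 9 = 153-dimensional vector.

CKSAAP
    Composition of k-spaced amino-acid pairs: for each k, counts of the
    21 x 21 = 441 ordered residue pairs (a, b) at positions (i, i+k+1).
    By default positions past the window end read as X, so a 17-mer
    yields exactly 17 pairs per k (the last ones pairing into the
    padding); with k in {0,1,2,3} the block is 441 x 4 = 1764-dimensional.

``encode_combined`` concatenates the requested encoder blocks per window
into a :class:`FeatureMatrix` with named columns and recorded block spans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .windows import ALPHABET, PeptideWindow

N_ALPHA = len(ALPHABET)  # 21
_CHAR_INDEX = {c: i for i, c in enumerate(ALPHABET)}
_PAIR_NAMES = [a + b for a in ALPHABET for b in ALPHABET]

#: Canonical block order in combined matrices.
ENCODER_ORDER = ("cksaap", "onehot", "aaindex")


@dataclass(frozen=True)
class AAindexTable:
    """Nine physicochemical property scales over the 21-letter alphabet.

    ``values[i, j]`` is property ``property_names[i]`` for residue
    ``ALPHABET[j]``; the final column is the padding residue X.
    """

    property_names: tuple[str, ...]
    values: np.ndarray  # (9, 21)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.property_names), N_ALPHA):
            raise ValueError(
                f"expected values of shape ({len(self.property_names)}, {N_ALPHA}), "
                f"got {v.shape}"
            )
        if not np.isfinite(v[:, : N_ALPHA - 1]).all():
            raise ValueError("non-finite property value for a standard amino acid")
        object.__setattr__(self, "values", v)

    @property
    def n_properties(self) -> int:
        return len(self.property_names)


def load_aaindex_table(
    path: str | Path | None = None, x_policy: str = "zero"
) -> AAindexTable:
    """Load the bundled (or a user-supplied) AAindex property table.

    The file is whitespace/tab-delimited text: one row per property, a
    name followed by 21 values in alphabet order, ``#`` lines ignored.
    ``x_policy`` sets the X (padding) column: ``"zero"`` keeps the value
    in the file, ``"mean"`` replaces it with the per-property mean over
    the 20 amino acids.
    """
    if path is None:
        src = resources.files("malprec.data").joinpath("aaindex_properties.tsv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    names: list[str] = []
    rows: list[list[float]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != N_ALPHA + 1:
            raise ValueError(
                f"AAindex row {parts[0]!r}: expected {N_ALPHA} values, got {len(parts) - 1}"
            )
        names.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    values = np.array(rows, dtype=float)
    if x_policy == "mean":
        values[:, -1] = values[:, :-1].mean(axis=1)
    elif x_policy != "zero":
        raise ValueError(f"unknown x_policy {x_policy!r}")
    return AAindexTable(property_names=tuple(names), values=values)


@dataclass(frozen=True)
class CKSAAPConfig:
    """Configuration of the k-spaced pair encoder.

    ``k_list`` is the set of gap sizes (k intervening residues between
    the pair members).  With ``pad_beyond_window`` (default) the pair
    index runs over every window position and partners past the window
    end read as X, giving window-length pairs per k; disabling it uses
    the conventional L-k-1 in-window pairs.  ``normalize`` divides each
    k-block by its pair count, turning counts into relative frequencies.
    """

    k_list: tuple[int, ...] = (0, 1, 2, 3)
    normalize: bool = False
    pad_beyond_window: bool = True

    def __post_init__(self) -> None:
        ks = tuple(sorted(set(int(k) for k in self.k_list)))
        if not ks:
            raise ValueError("k_list must be non-empty")
        if any(k < 0 for k in ks):
            raise ValueError("every k must be >= 0")
        object.__setattr__(self, "k_list", ks)

    def validate_for_length(self, length: int) -> None:
        if any(k > length - 1 for k in self.k_list):
            raise ValueError(
                f"k values {self.k_list} exceed window length {length} - 1"
            )


@dataclass
class FeatureMatrix:
    """A windows-by-features matrix with named columns and block provenance.

    ``block_spans`` maps encoder name to the half-open column range it
    occupies; ``config`` records the encoder settings needed to
    reproduce the matrix bit-for-bit.
    """

    values: np.ndarray
    column_names: list[str]
    block_spans: dict[str, tuple[int, int]]
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.column_names):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.column_names)} names"
            )
        if len(set(self.column_names)) != len(self.column_names):
            raise ValueError("column names must be unique")
        width = sum(b - a for a, b in self.block_spans.values())
        if width != self.values.shape[1]:
            raise ValueError("block spans do not tile the columns")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def block(self, name: str) -> np.ndarray:
        a, b = self.block_spans[name]
        return self.values[:, a:b]

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, columns=self.column_names).to_csv(path, index=False)

    def sidecar_config(self) -> dict:
        return {
            "alphabet": ALPHABET,
            "block_spans": {k: list(v) for k, v in self.block_spans.items()},
            **self.config,
        }


def _indices(window: PeptideWindow | str) -> np.ndarray:
    residues = window.residues if isinstance(window, PeptideWindow) else window
    try:
        return np.array([_CHAR_INDEX[c] for c in residues], dtype=np.intp)
    except KeyError as exc:
        c = exc.args[0]
        pos = residues.index(c)
        raise ValueError(
            f"residue {c!r} at window position {pos} is outside the alphabet"
        ) from None


def encode_onehot(window: PeptideWindow | str) -> np.ndarray:
    """Indicator encoding: one 21-dim block per position, single 1 per block."""
    idx = _indices(window)
    out = np.zeros((idx.size, N_ALPHA))
    out[np.arange(idx.size), idx] = 1.0
    return out.ravel()


def decode_onehot(vector: np.ndarray, length: int | None = None) -> str:
    """Invert :func:`encode_onehot` via per-block argmax."""
    v = np.asarray(vector, dtype=float)
    if v.size % N_ALPHA:
        raise ValueError(f"vector length {v.size} not a multiple of {N_ALPHA}")
    blocks = v.reshape(-1, N_ALPHA)
    if length is not None and blocks.shape[0] != length:
        raise ValueError("length mismatch")
    return "".join(ALPHABET[i] for i in blocks.argmax(axis=1))


def encode_aaindex(
    window: PeptideWindow | str, table: AAindexTable | None = None
) -> np.ndarray:
    """Physicochemical encoding: per position, the 9 property values."""
    if table is None:
        table = load_aaindex_table()
    idx = _indices(window)
    return table.values[:, idx].T.ravel()


def encode_cksaap(
    window: PeptideWindow | str, config: CKSAAPConfig | None = None
) -> np.ndarray:
    """K-spaced pair composition; one 441-length block per k, ks ascending.

    A pair for gap k joins positions (i, i+k+1).  In the default padded
    mode i covers every window position and partners beyond the last
    residue count as X, so each k-block holds exactly window-length
    pairs; in unpadded mode only fully in-window pairs are counted.
    With ``normalize`` each block is divided by its number of pairs.
    """
    if config is None:
        config = CKSAAPConfig()
    idx = _indices(window)
    L = idx.size
    config.validate_for_length(L)
    x = _CHAR_INDEX["X"]
    blocks = []
    for k in config.k_list:
        counts = np.zeros(N_ALPHA * N_ALPHA)
        if config.pad_beyond_window:
            partner = np.full(L, x, dtype=np.intp)
            in_range = np.arange(L) + k + 1 < L
            partner[in_range] = idx[np.arange(L)[in_range] + k + 1]
            pairs = idx * N_ALPHA + partner
        else:
            i = np.arange(L - k - 1)
            pairs = idx[i] * N_ALPHA + idx[i + k + 1]
        np.add.at(counts, pairs, 1.0)
        if config.normalize and pairs.size:
            counts /= pairs.size
        blocks.append(counts)
    return np.concatenate(blocks)


def cksaap_column_names(config: CKSAAPConfig) -> list[str]:
    return [f"cksaap_k{k}_{p}" for k in config.k_list for p in _PAIR_NAMES]


def onehot_column_names(length: int) -> list[str]:
    return [f"onehot_p{i}_{c}" for i in range(length) for c in ALPHABET]


def aaindex_column_names(length: int, table: AAindexTable) -> list[str]:
    return [f"aaindex_p{i}_{name}" for i in range(length) for name in table.property_names]


def encode_combined(
    windows: list[PeptideWindow],
    config: CKSAAPConfig | None = None,
    encoders: tuple[str, ...] = ENCODER_ORDER,
    table: AAindexTable | None = None,
    window_length: int | None = None,
) -> FeatureMatrix:
    """Encode windows into a single matrix of concatenated feature blocks.

    Blocks appear in the canonical order CKSAAP, one-hot, AAindex
    (restricted to ``encoders``).  For the default 17-mer configuration
    the width is 1764 + 357 + 153 = 2274.  An empty window list yields a
    0-row matrix with full column metadata, provided ``window_length``
    is given (default 17).
    """
    unknown = set(encoders) - set(ENCODER_ORDER)
    if unknown:
        raise ValueError(f"unknown encoders: {sorted(unknown)}")
    encoders = tuple(e for e in ENCODER_ORDER if e in encoders)
    if not encoders:
        raise ValueError("at least one encoder required")
    if config is None:
        config = CKSAAPConfig()
    if table is None and "aaindex" in encoders:
        table = load_aaindex_table()

    lengths = {len(w) for w in windows}
    if len(lengths) > 1:
        raise ValueError(f"mixed window lengths: {sorted(lengths)}")
    if lengths:
        L = lengths.pop()
        if window_length is not None and window_length != L:
            raise ValueError("window_length disagrees with the windows")
    else:
        L = 17 if window_length is None else window_length

    names: list[str] = []
    spans: dict[str, tuple[int, int]] = {}
    for enc in encoders:
        start = len(names)
        if enc == "cksaap":
            names += cksaap_column_names(config)
        elif enc == "onehot":
            names += onehot_column_names(L)
        else:
            names += aaindex_column_names(L, table)
        spans[enc] = (start, len(names))

    rows = np.empty((len(windows), len(names)))
    for r, w in enumerate(windows):
        parts = []
        for enc in encoders:
            if enc == "cksaap":
                parts.append(encode_cksaap(w, config))
            elif enc == "onehot":
                parts.append(encode_onehot(w))
            else:
                parts.append(encode_aaindex(w, table))
        rows[r] = np.concatenate(parts)

    meta = {
        "encoders": list(encoders),
        "window_length": L,
        "cksaap": {
            "k_list": list(config.k_list),
            "normalize": config.normalize,
            "pad_beyond_window": config.pad_beyond_window,
        },
    }
    if "aaindex" in encoders:
        meta["aaindex_properties"] = list(table.property_names)
    return FeatureMatrix(values=rows, column_names=names, block_spans=spans, config=meta)
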