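"""Feature encodings for fixed-length DNA windows.

Five encoders are provided:

``binary``
    One-hot per position in (A, C, G, T) order; 4·L features.
``kmer``
    Normalized overlapping k-mer frequencies, lexicographic over A<C<G<T;
    4^k features summing to 1 per sequence.
``ncp``
    Nucleotide chemical property code, 3 bits per base reflecting ring
    structure, hydrogen bonding, and functional group: A→(1,1,1),
    C→(0,1,0), G→(1,0,0), T→(0,0,1); 3·L features.
``enac``
    Enhanced nucleotide composition: base frequencies in a width-w window
    slid with stride 1; (L−w+1)·4 features.
``pstnpds``
    Position-Specific TriNucleotide Propensity over the double-strand
    (strand-reduced) alphabet. Watson–Crick pairing identifies A with T and
    C with G, so each window reduces to a two-letter {A,C} string with
    2^3 = 8 possible trinucleotides per position. A fitted model holds, for
    every position j ∈ 1..L−2 and reduced trinucleotide i ∈ 1..8, the
    class-conditional frequencies F⁺(i|j) and F⁻(i|j) estimated from a
    labeled training set, and their difference z(i,j) = F⁺(i|j) − F⁻(i|j).
    A window is encoded as the length-(L−2) vector of z-values picked out
    by its own trinucleotides — positive where its local context is more
    typical of methylated windows, negative where it is more typical of the
    background.

PSTNPds is a fit/transform pair: the frequencies are label statistics, so
in cross-validation they must be estimated on the training split only (the
pipeline module enforces this; see its ``leak_mode``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .datasets import LabeledDataset
from .errors import AlphabetError, FitError, LengthMismatchError, ParameterError

__all__ = [
    "FeatureMatrix",
    "PSTNPdsModel",
    "encode_binary",
    "encode_kmer",
    "encode_ncp",
    "encode_enac",
    "reduce_strand",
    "trinucleotide_index",
    "fit_pstnpds",
    "transform_pstnpds",
    "TRI_ORDER",
]

_BASE_ORDER = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASE_ORDER)}

# Chemical-property code: (ring structure, hydrogen bonding, functional group)
_NCP_CODE = {"A": (1, 1, 1), "C": (0, 1, 0), "G": (1, 0, 0), "T": (0, 0, 1)}

# Strand reduction: complementary pairing identifies T with A and G with C.
_REDUCE = str.maketrans({"T": "A", "G": "C"})

#: Reduced trinucleotides in lexicographic order (A < C); row order of Z.
TRI_ORDER: tuple[str, ...] = tuple("".join(t) for t in product("AC", repeat=3))


@dataclass
class FeatureMatrix:
    """n_samples × n_features real matrix with provenance.

    Row order matches the input record order; ``feature_names`` has exactly
    ``n_features`` entries. Positions in feature names are 1-based.
    """

    values: np.ndarray
    feature_names: list[str]
    encoder_id: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n_samples, n_features)")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.feature_names)} feature names"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def _pos_label(i: int, width: int) -> str:
    return f"pos{i:0{width}d}"


def _require_nonempty(ds: LabeledDataset) -> int:
    if len(ds) == 0 or ds.length is None:
        raise ParameterError("cannot encode an empty dataset")
    return ds.length


# ---------------------------------------------------------------------------
# Classical encoders
# ---------------------------------------------------------------------------

def encode_binary(ds: LabeledDataset) -> FeatureMatrix:
    """One-hot encoding, 4 bits per position in (A, C, G, T) order."""
    L = _require_nonempty(ds)
    width = max(2, len(str(L)))
    out = np.zeros((len(ds), 4 * L))
    for r, rec in enumerate(ds):
        for j, b in enumerate(rec.seq):
            out[r, 4 * j + _BASE_IDX[b]] = 1.0
    names = [f"{_pos_label(j + 1, width)}_{b}" for j in range(L) for b in _BASE_ORDER]
    return FeatureMatrix(out, names, "binary", {"L": L})


def encode_kmer(ds: LabeledDataset, k: int = 3) -> FeatureMatrix:
    """Overlapping k-mer frequencies: f_t = N_t / (L − k + 1).

    Features are the 4^k k-mers in lexicographic (A<C<G<T) order; each row
    sums to 1.
    """
    L = _require_nonempty(ds)
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if k > L:
        raise ParameterError(f"k={k} exceeds the window length L={L}")
    kmers = ["".join(t) for t in product(_BASE_ORDER, repeat=k)]
    index = {m: i for i, m in enumerate(kmers)}
    n_windows = L - k + 1
    out = np.zeros((len(ds), len(kmers)))
    for r, rec in enumerate(ds):
        for j in range(n_windows):
            out[r, index[rec.seq[j : j + k]]] += 1.0
    out /= n_windows
    return FeatureMatrix(out, kmers, "kmer", {"k": k, "L": L})


def encode_ncp(ds: LabeledDataset) -> FeatureMatrix:
    """Nucleotide chemical property code, 3 bits per position."""
    L = _require_nonempty(ds)
    width = max(2, len(str(L)))
    out = np.zeros((len(ds), 3 * L))
    for r, rec in enumerate(ds):
        for j, b in enumerate(rec.seq):
            out[r, 3 * j : 3 * j + 3] = _NCP_CODE[b]
    props = ("ring", "hbond", "func")
    names = [f"{_pos_label(j + 1, width)}_{p}" for j in range(L) for p in props]
    return FeatureMatrix(out, names, "ncp", {"L": L})


def encode_enac(ds: LabeledDataset, window: int = 5) -> FeatureMatrix:
    """Enhanced nucleotide composition in sliding windows of width *window*.

    Windows start at position 1 and slide with stride 1; within each window
    the four base frequencies (count / window) are emitted, so every
    4-block sums to 1 and there are (L − window + 1)·4 features.
    """
    L = _require_nonempty(ds)
    if window < 1:
        raise ParameterError(f"window must be >= 1, got {window}")
    if window > L:
        raise ParameterError(f"window={window} exceeds the window length L={L}")
    n_win = L - window + 1
    width = max(2, len(str(n_win)))
    out = np.zeros((len(ds), 4 * n_win))
    for r, rec in enumerate(ds):
        for j in range(n_win):
            for b in rec.seq[j : j + window]:
                out[r, 4 * j + _BASE_IDX[b]] += 1.0
    out /= window
    names = [f"win{j + 1:0{width}d}_{b}" for j in range(n_win) for b in _BASE_ORDER]
    return FeatureMatrix(out, names, "enac", {"window": window, "L": L})


# ---------------------------------------------------------------------------
# PSTNPds
# ---------------------------------------------------------------------------

def reduce_strand(seq: str) -> str:
    """Collapse a DNA string onto the strand-reduced alphabet {A, C}.

    Complementary pairing identifies T with A and G with C, positionwise;
    length is preserved and the map is idempotent.
    """
    bad = set(seq) - set("ACGT")
    if bad:
        raise AlphabetError(f"invalid character(s) {sorted(bad)} in sequence")
    return seq.translate(_REDUCE)


def trinucleotide_index(tri: str) -> int:
    """1-based lexicographic rank (A < C) of a reduced trinucleotide.

    AAA→1, AAC→2, ..., CCC→8.
    """
    if len(tri) != 3 or set(tri) - {"A", "C"}:
        raise AlphabetError(
            f"expected a length-3 string over the reduced alphabet {{A,C}}, got {tri!r}"
        )
    return 1 + sum((1 if b == "C" else 0) << (2 - i) for i, b in enumerate(tri))


def _tri_indices(seq: str) -> np.ndarray:
    """0-based reduced-trinucleotide index at every start position of *seq*."""
    bits = np.frombuffer(reduce_strand(seq).encode(), dtype=np.uint8) == ord("C")
    bits = bits.astype(np.int64)
    return 4 * bits[:-2] + 2 * bits[1:-1] + bits[2:]


@dataclass
class PSTNPdsModel:
    """Fitted position-specific trinucleotide propensity matrices.

    ``f_pos`` and ``f_neg`` are 8 × (L−2) class-conditional frequency
    matrices (each column sums to 1: every training window contributes
    exactly one reduced trinucleotide per position); ``z = f_pos − f_neg``,
    entrywise in [−1, 1]. ``train_fingerprint`` records the training
    records the frequencies were estimated on.
    """

    L: int
    f_pos: np.ndarray
    f_neg: np.ndarray
    z: np.ndarray
    tri_order: tuple[str, ...] = TRI_ORDER
    train_fingerprint: str | None = None

    def to_json(self, path) -> None:
        payload = {
            "L": self.L,
            "f_pos": self.f_pos.tolist(),
            "f_neg": self.f_neg.tolist(),
            "z": self.z.tolist(),
            "tri_order": list(self.tri_order),
            "train_fingerprint": self.train_fingerprint,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PSTNPdsModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls.from_dict(payload)

    def to_dict(self) -> dict:
        return {
            "L": self.L,
            "f_pos": self.f_pos.tolist(),
            "f_neg": self.f_neg.tolist(),
            "z": self.z.tolist(),
            "tri_order": list(self.tri_order),
            "train_fingerprint": self.train_fingerprint,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PSTNPdsModel":
        return cls(
            L=int(payload["L"]),
            f_pos=np.asarray(payload["f_pos"], dtype=float),
            f_neg=np.asarray(payload["f_neg"], dtype=float),
            z=np.asarray(payload["z"], dtype=float),
            tri_order=tuple(payload["tri_order"]),
            train_fingerprint=payload.get("train_fingerprint"),
        )


def fit_pstnpds(train: LabeledDataset) -> PSTNPdsModel:
    """Estimate F⁺, F⁻ and Z from a labeled training set.

    For every position j and reduced trinucleotide i,
    ``f_pos[i, j]`` is the fraction of positive training windows whose
    reduced trinucleotide starting at j is i; ``f_neg`` analogously over
    negatives; ``z = f_pos − f_neg``.
    """
    L = _require_nonempty(train)
    if L < 3:
        raise ParameterError(f"PSTNPds requires L >= 3, got {L}")
    if train.n_pos < 1 or train.n_neg < 1:
        raise FitError(
            f"PSTNPds requires both classes in the training set "
            f"(got n_pos={train.n_pos}, n_neg={train.n_neg})"
        )
    counts = {0: np.zeros((8, L - 2)), 1: np.zeros((8, L - 2))}
    cols = np.arange(L - 2)
    for rec in train:
        np.add.at(counts[rec.label], (_tri_indices(rec.seq), cols), 1.0)
    f_pos = counts[1] / train.n_pos
    f_neg = counts[0] / train.n_neg
    return PSTNPdsModel(
        L=L, f_pos=f_pos, f_neg=f_neg, z=f_pos - f_neg,
        train_fingerprint=train.fingerprint(),
    )


def transform_pstnpds(model: PSTNPdsModel, ds: LabeledDataset) -> FeatureMatrix:
    """Encode each window as its length-(L−2) vector of z-lookups."""
    L = _require_nonempty(ds)
    if L != model.L:
        raise LengthMismatchError(
            f"dataset windows have length {L} but the model was fitted on L={model.L}"
        )
    cols = np.arange(L - 2)
    out = np.empty((len(ds), L - 2))
    for r, rec in enumerate(ds):
        out[r] = model.z[_tri_indices(rec.seq), cols]
    width = max(2, len(str(L - 2)))
    names = [f"phi_{u + 1:0{width}d}" for u in range(L - 2)]
    return FeatureMatrix(out, names, "pstnpds", {"L": L})


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

ENCODER_NAMES = ("binary", "kmer", "ncp", "enac", "pstnpds")


def encode(
    ds: LabeledDataset,
    encoder: str,
    *,
    k: int = 3,
    window: int = 5,
    pstnp_model: PSTNPdsModel | None = None,
) -> FeatureMatrix:
    """Run one of the five encoders by name.

    ``pstnpds`` requires a fitted :class:`PSTNPdsModel` (fit it on the
    training split only).
    """
    if encoder == "binary":
        return encode_binary(ds)
    if encoder == "kmer":
        return encode_kmer(ds, k=k)
    if encoder == "ncp":
        return encode_ncp(ds)
    if encoder == "enac":
        return encode_enac(ds, window=window)
    if encoder == "pstnpds":
        if pstnp_model is None:
            raise ParameterError("encoder 'pstnpds' requires a fitted PSTNPdsModel")
        return transform_pstnpds(pstnp_model, ds)
    raise ParameterError(f"unknown encoder {encoder!r}; choose from {ENCODER_NAMES}")
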