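"""Sequence feature encoders: KNFC, MNBE and the natural vector.

Three schemes, each mapping a :class:`~sixma.seqio.SampleWindow` to a
named numeric vector:

* ``knfc`` — frequencies of all overlapping k-tuples, one block of 4^k
  features per requested k, lexicographic over (A, C, G, T); each block
  is normalised by the number of k-tuple slots (L - k + 1) so it sums
  to 1 (raw counts available via ``normalize=False``).
* ``mnbe`` — per-position 4-bit one-hot code, A=(1,0,0,0), C=(0,1,0,0),
  G=(0,0,1,0), T=(0,0,0,1); 4·L features in sequence order.
* ``nv``   — 12 numbers: for each nucleotide R its count ``n_R``, mean
  1-based position ``mu_R`` and second-order normalised central moment
  ``d2_R = sum_i (pos_i - mu_R)^2 / (L * n_R)``.  Bases absent from the
  window get (count, mean, moment) = (0, 0, 0).

All encoders are pure: identical input gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from sixma.seqio import SampleWindow, _normalize

SequenceLike = Union[SampleWindow, str]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

SCHEMES = ("knfc", "mnbe", "nv")

DEFAULT_K_VALUES = (2, 3, 4)


@dataclass(frozen=True)
class FeatureVector:
    """A scheme-tagged, named, ordered numeric encoding of one window."""

    scheme: str
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError(
                f"values/names length mismatch: {len(self.values)} != {len(self.names)}"
            )

    def __len__(self) -> int:
        return len(self.values)


def _seq_of(window: SequenceLike) -> str:
    """Accept a validated window or a bare DNA string (alphabet-checked)."""
    if isinstance(window, SampleWindow):
        return window.seq
    return _normalize(window)


def kmer_names(k: int) -> list[str]:
    """All 4^k k-mers in lexicographic (A, C, G, T) order."""
    return ["".join(t) for t in product(BASES, repeat=k)]


def encode_knfc(
    window: SequenceLike,
    k_values: Sequence[int] = DEFAULT_K_VALUES,
    normalize: bool = True,
) -> FeatureVector:
    """K-tuple nucleotide frequency component.

    For each k the block holds the overlapping-count frequency of every
    k-mer: ``count(t) / (L - k + 1)``.  Blocks are concatenated in
    ascending k order.  ``k >= L`` is a parameter error.
    """
    seq = _seq_of(window)
    L = len(seq)
    ks = sorted(k_values)
    if len(set(ks)) != len(ks):
        raise ValueError(f"duplicate k values in {list(k_values)}")
    for k in ks:
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        if k >= L:
            raise ValueError(f"k={k} must be smaller than window length {L}")
    codes = np.fromiter((_BASE_INDEX[c] for c in seq), dtype=np.int64, count=L)
    blocks: list[np.ndarray] = []
    names: list[str] = []
    for k in ks:
        # integer-encode every k-mer slot in base 4, then bincount
        idx = np.zeros(L - k + 1, dtype=np.int64)
        for j in range(k):
            idx = idx * 4 + codes[j : L - k + 1 + j]
        counts = np.bincount(idx, minlength=4**k).astype(float)
        if normalize:
            counts /= L - k + 1
        blocks.append(counts)
        names.extend(f"knfc_k{k}_{mer}" for mer in kmer_names(k))
    return FeatureVector("knfc", np.concatenate(blocks), tuple(names))


def encode_mnbe(window: SequenceLike) -> FeatureVector:
    """Mono-nucleotide binary encoding: 4·L one-hot features."""
    seq = _seq_of(window)
    L = len(seq)
    values = np.zeros(4 * L)
    for i, ch in enumerate(seq):
        values[4 * i + _BASE_INDEX[ch]] = 1.0
    names = tuple(f"mnbe_p{i + 1}_{b}" for i in range(L) for b in BASES)
    return FeatureVector("mnbe", values, names)


def decode_mnbe(values: np.ndarray) -> str:
    """Invert :func:`encode_mnbe` (used as a bijectivity check)."""
    mat = np.asarray(values).reshape(-1, 4)
    if not np.all(mat.sum(axis=1) == 1):
        raise ValueError("not a valid one-hot encoding: a 4-block sum != 1")
    return "".join(BASES[j] for j in mat.argmax(axis=1))


def encode_nv(window: SequenceLike, moment_denominator: str = "length") -> FeatureVector:
    """Natural vector: (count, mean position, central moment) per base.

    ``moment_denominator`` selects the normalisation of the second-order
    central moment: ``"length"`` (default) divides by ``L * n_R``;
    ``"count"`` divides by ``n_R * n_R`` (the alternative reading of the
    ambiguous printed denominator).
    """
    if moment_denominator not in ("length", "count"):
        raise ValueError(f"unknown moment_denominator {moment_denominator!r}")
    seq = _seq_of(window)
    L = len(seq)
    values: list[float] = []
    names: list[str] = []
    for base in BASES:
        positions = np.flatnonzero(np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)) + 1
        n_r = len(positions)
        if n_r == 0:
            mu, d2 = 0.0, 0.0
        else:
            mu = positions.sum() / n_r
            denom = L * n_r if moment_denominator == "length" else n_r * n_r
            d2 = float(np.sum((positions - mu) ** 2) / denom)
        values.extend((float(n_r), float(mu), d2))
        names.extend((f"nv_n_{base}", f"nv_mu_{base}", f"nv_d2_{base}"))
    return FeatureVector("nv", np.array(values), tuple(names))


_ENCODER_DISPATCH = {
    "knfc": encode_knfc,
    "mnbe": encode_mnbe,
    "nv": encode_nv,
}


def encode_combined(
    window: SequenceLike,
    schemes: Sequence[str],
    k_values: Sequence[int] = DEFAULT_K_VALUES,
) -> FeatureVector:
    """Concatenate single-scheme encodings in the given order.

    ``schemes`` must be non-empty, drawn from {knfc, mnbe, nv} and free
    of duplicates.  Feature names carry their scheme prefix so column
    identity is unambiguous after concatenation.
    """
    tags = [s.lower() for s in schemes]
    if not tags:
        raise ValueError("schemes must be non-empty")
    unknown = [s for s in tags if s not in SCHEMES]
    if unknown:
        raise ValueError(f"unknown scheme(s) {unknown}; expected subset of {SCHEMES}")
    if len(set(tags)) != len(tags):
        raise ValueError(f"duplicate scheme(s) in {tags}")
    parts = []
    for tag in tags:
        if tag == "knfc":
            parts.append(encode_knfc(window, k_values=k_values))
        else:
            parts.append(_ENCODER_DISPATCH[tag](window))
    if len(parts) == 1:
        return parts[0]
    return FeatureVector(
        "+".join(tags),
        np.concatenate([p.values for p in parts]),
        tuple(n for p in parts for n in p.names),
    )


def encode_matrix(
    windows: Iterable[SampleWindow],
    schemes: Sequence[str],
    k_values: Sequence[int] = DEFAULT_K_VALUES,
    with_labels: bool = False,
) -> pd.DataFrame:
    """Encode many windows into a feature matrix (rows indexed by id).

    With ``with_labels=True`` a final ``label`` column is appended;
    every window must then be labelled.
    """
    rows = []
    index = []
    labels = []
    names: tuple[str, ...] | None = None
    for w in windows:
        fv = encode_combined(w, schemes, k_values=k_values)
        if names is None:
            names = fv.names
        elif fv.names != names:
            raise ValueError("inconsistent feature names across windows (mixed lengths?)")
        rows.append(fv.values)
        index.append(w.id)
        if with_labels:
            if w.label is None:
                raise ValueError(f"window {w.id!r} has no label")
            labels.append(w.label)
    if names is None:
        raise ValueError("no windows to encode")
    df = pd.DataFrame(np.vstack(rows), index=pd.Index(index, name="id"), columns=list(names))
    if with_labels:
        df["label"] = labels
    return df
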