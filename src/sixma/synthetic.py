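"""Deterministic labelled fixture generation.

Windows are 41 nt with a central adenine.  Both classes are stratified
to the same central-motif ratios, so the centre carries no label signal
by construction; the learnable signal is a positional composition bias
in the positive class, controlled continuously by ``bias_strength``
(0 = null: classes identically distributed; 1 = full tilt).  Biased
flank offsets default to -8..+10 and +15..+18 relative to the centre,
with a stronger A-enrichment over the -4..-1 block (an upstream
A-run preference).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from sixma.dataset import (
    MOTIF_CLASSES,
    MotifRatios,
    largest_remainder_apportionment,
)
from sixma.seqio import SampleWindow

BASES = "ACGT"

_UNIFORM = np.full(4, 0.25)
# Tilt targets: A-enriched flank profile, stronger over the upstream A-run.
_BIASED_PROFILE = np.array([0.55, 0.15, 0.15, 0.15])
_ARUN_PROFILE = np.array([0.85, 0.05, 0.05, 0.05])

DEFAULT_BIASED_OFFSETS = tuple(range(-8, 11)) + tuple(range(15, 19))
DEFAULT_ARUN_OFFSETS = (-4, -3, -2, -1)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic labelled dataset."""

    n_pos: int
    n_neg: int
    ratios: MotifRatios = MotifRatios()
    bias_strength: float = 0.8
    biased_offsets: tuple[int, ...] = DEFAULT_BIASED_OFFSETS
    arun_offsets: tuple[int, ...] = DEFAULT_ARUN_OFFSETS
    length: int = 41
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("n_pos and n_neg must be non-negative")
        if not 0.0 <= self.bias_strength <= 1.0:
            raise ValueError(f"bias_strength must be in [0, 1], got {self.bias_strength}")
        if self.length < 5 or self.length % 2 == 0:
            raise ValueError(f"length must be odd and >= 5, got {self.length}")
        flank = (self.length - 1) // 2
        for off in self.biased_offsets + self.arun_offsets:
            if not -flank <= off <= flank:
                raise ValueError(f"offset {off} outside window of flank {flank}")


def _position_profiles(spec: SyntheticSpec, positive: bool) -> np.ndarray:
    """Per-position nucleotide distributions (length x 4)."""
    profiles = np.tile(_UNIFORM, (spec.length, 1))
    if positive and spec.bias_strength > 0:
        centre = (spec.length - 1) // 2  # 0-based
        b = spec.bias_strength
        for off in spec.biased_offsets:
            profiles[centre + off] = (1 - b) * _UNIFORM + b * _BIASED_PROFILE
        for off in spec.arun_offsets:
            profiles[centre + off] = (1 - b) * _UNIFORM + b * _ARUN_PROFILE
    return profiles


def _impose_stratum(seq: list[str], centre: int, motif: str, rng: np.random.Generator) -> None:
    """Rewrite the central context in place so the window falls in ``motif``.

    The motif classes are nested, so less specific strata must also
    exclude the more specific match (e.g. an AGG window must not have G
    immediately upstream, which would promote it to GAGG).
    """
    seq[centre] = "A"
    not_g = "ACT"
    if motif == "GAGG":
        seq[centre - 1] = "G"
        seq[centre + 1] = "G"
        seq[centre + 2] = "G"
    elif motif == "AGG":
        seq[centre + 1] = "G"
        seq[centre + 2] = "G"
        if seq[centre - 1] == "G":
            seq[centre - 1] = not_g[rng.integers(3)]
    elif motif == "AG":
        seq[centre + 1] = "G"
        if seq[centre + 2] == "G":
            seq[centre + 2] = not_g[rng.integers(3)]
    else:  # other
        if seq[centre + 1] == "G":
            seq[centre + 1] = not_g[rng.integers(3)]


def _generate_class(
    spec: SyntheticSpec,
    n: int,
    positive: bool,
    rng: np.random.Generator,
) -> list[SampleWindow]:
    profiles = _position_profiles(spec, positive)
    cum3 = np.cumsum(profiles, axis=1)[:, :3]  # inversion thresholds per position
    centre = (spec.length - 1) // 2
    per_stratum = largest_remainder_apportionment(n, spec.ratios.as_tuple())
    label = 1 if positive else 0
    tag = "pos" if positive else "neg"
    windows: list[SampleWindow] = []
    counter = 0
    for motif, count in zip(MOTIF_CLASSES, per_stratum):
        if count == 0:
            continue
        u = rng.random((count, spec.length))
        draws = (u[:, :, None] >= cum3[None, :, :]).sum(axis=2)
        for j in range(count):
            seq = [BASES[b] for b in draws[j]]
            _impose_stratum(seq, centre, motif, rng)
            counter += 1
            windows.append(
                SampleWindow(id=f"{tag}_{counter:06d}", seq="".join(seq), label=label)
            )
    return windows


def generate(spec: SyntheticSpec) -> list[SampleWindow]:
    """Generate the labelled dataset described by ``spec``.

    Fully deterministic given ``spec.seed``.  Positives come first, in
    stratum order GAGG, AGG, AG, other; shuffle downstream if order
    matters.
    """
    rng = np.random.default_rng(spec.seed)
    positives = _generate_class(spec, spec.n_pos, True, rng)
    negatives = _generate_class(spec, spec.n_neg, False, rng)
    return positives + negatives


def position_composition(windows: Sequence[SampleWindow]) -> pd.DataFrame:
    """Class-conditional per-position nucleotide frequencies.

    Returns a DataFrame indexed by (label, position) — position 1-based
    — with one column per nucleotide; each row sums to 1.  Requires
    labelled windows and at least one window per present class.
    """
    if not windows:
        raise ValueError("no windows given")
    by_label: dict[int, list[SampleWindow]] = {}
    for w in windows:
        if w.label is None:
            raise ValueError(f"window {w.id!r} has no label")
        by_label.setdefault(w.label, []).append(w)
    lengths = {len(w.seq) for w in windows}
    if len(lengths) != 1:
        raise ValueError(f"windows must share one length, got {sorted(lengths)}")
    L = lengths.pop()
    rows = []
    index = []
    for label in sorted(by_label):
        group = by_label[label]
        mat = np.frombuffer("".join(w.seq for w in group).encode(), dtype=np.uint8)
        mat = mat.reshape(len(group), L)
        for pos in range(L):
            col = mat[:, pos]
            freqs = [float((col == ord(b)).mean()) for b in BASES]
            rows.append(freqs)
            index.append((label, pos + 1))
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["label", "position"]),
        columns=list(BASES),
    )
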