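"""Benchmark-construction logic.

Central-motif stratification, motif-ratio-matched negative sampling,
greedy identity filtering and class balancing.  Motif classes are
anchored at the central adenine and nested most-specific-first
(GAGG > AGG > AG > other), so every window belongs to exactly one
stratum.  All sampling takes one explicit integer seed per call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from sixma.seqio import SampleWindow

MOTIF_CLASSES = ("GAGG", "AGG", "AG", "other")

# Published stratum proportions of the positive benchmark:
# GAGG 26,300/154,000 = 17.08%, AGG 24,264 = 15.76%, AG 22,206 = 14.42%.
DEFAULT_P_GAGG = 0.1708
DEFAULT_P_AGG = 0.1576
DEFAULT_P_AG = 0.1442


@dataclass(frozen=True)
class MotifRatios:
    """Target stratum proportions for GAGG / AGG / AG / other."""

    p_gagg: float = DEFAULT_P_GAGG
    p_agg: float = DEFAULT_P_AGG
    p_ag: float = DEFAULT_P_AG
    p_other: float = 1.0 - DEFAULT_P_GAGG - DEFAULT_P_AGG - DEFAULT_P_AG

    def __post_init__(self) -> None:
        probs = self.as_tuple()
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError(f"proportions must lie in [0, 1]: {probs}")
        total = sum(probs)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {total!r}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.p_gagg, self.p_agg, self.p_ag, self.p_other)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(MOTIF_CLASSES, self.as_tuple()))


def classify_central_motif(window: SampleWindow) -> str:
    """Return the motif stratum of the window's central adenine.

    Most-specific match anchored at the centre ``c`` (1-based):
    ``GAGG`` if seq[c-1..c+2] == GAGG, else ``AGG`` if seq[c..c+2] ==
    AGG, else ``AG`` if seq[c..c+1] == AG, else ``other``.
    """
    seq = window.seq
    c = window.centre - 1  # 0-based centre index
    if seq[c - 1 : c + 3] == "GAGG":
        return "GAGG"
    if seq[c : c + 3] == "AGG":
        return "AGG"
    if seq[c : c + 2] == "AG":
        return "AG"
    return "other"


def stratum_counts(windows: Sequence[SampleWindow]) -> dict[str, int]:
    """Count windows per motif stratum (a partition of the input)."""
    counts = dict.fromkeys(MOTIF_CLASSES, 0)
    for w in windows:
        counts[classify_central_motif(w)] += 1
    return counts


def largest_remainder_apportionment(n: int, proportions: Sequence[float]) -> list[int]:
    """Integer counts summing exactly to ``n`` with quotas ``n * p``.

    Each class gets ``floor(n * p)``; remaining units go to the classes
    with the largest fractional remainders (ties broken by class order).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    quotas = [n * p for p in proportions]
    counts = [int(np.floor(q)) for q in quotas]
    shortfall = n - sum(counts)
    remainders = sorted(
        range(len(proportions)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in remainders[:shortfall]:
        counts[i] += 1
    return counts


def sample_matched_negatives(
    candidates: Sequence[SampleWindow],
    ratios: MotifRatios,
    n: int,
    seed: int,
) -> list[SampleWindow]:
    """Stratified sample of ``n`` candidates matching ``ratios``.

    Stratum counts are the largest-remainder apportionment of
    ``n * p`` so they sum to ``n`` exactly.  Sampling is uniform without
    replacement within each stratum and deterministic given ``seed``.
    A stratum with too few candidates raises, naming the shortfall.
    """
    required = dict(zip(MOTIF_CLASSES, largest_remainder_apportionment(n, ratios.as_tuple())))
    by_stratum: dict[str, list[int]] = {m: [] for m in MOTIF_CLASSES}
    for i, w in enumerate(candidates):
        by_stratum[classify_central_motif(w)].append(i)
    for motif, need in required.items():
        have = len(by_stratum[motif])
        if have < need:
            raise ValueError(
                f"stratum {motif!r}: need {need} candidates, only {have} available "
                f"(short by {need - have})"
            )
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for motif in MOTIF_CLASSES:
        pool = np.array(by_stratum[motif], dtype=np.int64)
        chosen.extend(rng.choice(pool, size=required[motif], replace=False))
    chosen.sort()  # preserve candidate order in the output
    return [candidates[i] for i in chosen]


def greedy_identity_filter(
    windows: Sequence[SampleWindow],
    threshold: float = 0.8,
) -> list[SampleWindow]:
    """Greedy redundancy removal by ungapped identity.

    Windows are visited in input order; a window is kept iff its
    positional identity (matching positions / length) with every
    previously kept window is strictly below ``threshold``.  At
    ``threshold=1.0`` only exact duplicates are removed.

    This is a documented stand-in for CD-HIT, which uses word-filtered
    alignment identity and length-sorted greedy clustering; results are
    NOT interchangeable with CD-HIT output.  Full-scale benchmark
    rebuilding should run CD-HIT externally.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if not windows:
        return []
    lengths = {len(w.seq) for w in windows}
    if len(lengths) != 1:
        raise ValueError(f"windows must share one length, got lengths {sorted(lengths)}")
    L = lengths.pop()
    mats = np.frombuffer("".join(w.seq for w in windows).encode(), dtype=np.uint8)
    mats = mats.reshape(len(windows), L)
    kept_idx: list[int] = []
    kept_rows: list[np.ndarray] = []
    for i in range(len(windows)):
        row = mats[i]
        if kept_rows:
            identities = (np.vstack(kept_rows) == row).mean(axis=1)
            if float(identities.max()) >= threshold:
                continue
        kept_idx.append(i)
        kept_rows.append(row)
    return [windows[i] for i in kept_idx]


def balance_classes(
    pos: Sequence[SampleWindow],
    neg: Sequence[SampleWindow],
    seed: int,
) -> tuple[list[SampleWindow], list[SampleWindow]]:
    """Subsample negatives without replacement down to ``len(pos)``."""
    if len(neg) < len(pos):
        raise ValueError(
            f"need at least {len(pos)} negative candidates, got {len(neg)}"
        )
    if len(neg) == len(pos):
        return list(pos), list(neg)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(neg), size=len(pos), replace=False))
    return list(pos), [neg[i] for i in idx]
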