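"""FASTA and labelled-table I/O plus adenine-centred window extraction.

Coordinates are 1-based and fully closed throughout: the centre of a
41-nt window is position 21.  Lowercase input is uppercased; any other
character (including ``N``) is rejected rather than skipped, because
silent coercion would corrupt downstream encodings.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGT")
DEFAULT_FLANK = 20
DEFAULT_LENGTH = 2 * DEFAULT_FLANK + 1

PathLike = Union[str, Path]


class FastaFormatError(ValueError):
    """Raised when a FASTA file is structurally malformed."""


class SequenceValidationError(ValueError):
    """Raised when a sequence violates the {A,C,G,T} alphabet."""


class TableFormatError(ValueError):
    """Raised when a labelled sample table violates its schema."""


class WindowValidationError(ValueError):
    """Raised when a window violates the SampleWindow invariants."""


def _normalize(seq: str) -> str:
    """Uppercase ``seq`` and reject characters outside {A,C,G,T}."""
    up = seq.upper()
    bad = [(i + 1, ch) for i, ch in enumerate(up) if ch not in DNA_ALPHABET]
    if bad:
        shown = ", ".join(f"{ch!r}@{pos}" for pos, ch in bad[:10])
        more = "" if len(bad) <= 10 else f" (+{len(bad) - 10} more)"
        raise SequenceValidationError(
            f"sequence contains non-ACGT characters: {shown}{more}"
        )
    return up


@dataclass(frozen=True)
class SampleWindow:
    """A validated fixed-length DNA window with a central adenine.

    Parameters
    ----------
    id:
        Text identifier of the window.
    seq:
        DNA string over {A,C,G,T}; must have odd length with ``A`` at the
        centre.  Lowercase input is accepted and uppercased.
    label:
        Optional binary label: 1 = methylated (6mA), 0 = unmethylated.
    source_pos:
        Optional 1-based coordinate of the central base in the sequence
        the window was cut from.
    """

    id: str
    seq: str
    label: Optional[int] = None
    source_pos: Optional[int] = None

    def __post_init__(self) -> None:
        seq = _normalize(self.seq)
        object.__setattr__(self, "seq", seq)
        n = len(seq)
        if n < 3 or n % 2 == 0:
            raise WindowValidationError(
                f"window {self.id!r}: length must be odd and >= 3, got {n}"
            )
        centre = seq[(n - 1) // 2]
        if centre != "A":
            raise WindowValidationError(
                f"window {self.id!r}: centre base is {centre!r}, expected 'A'"
            )
        if self.label is not None and self.label not in (0, 1):
            raise WindowValidationError(
                f"window {self.id!r}: label must be 0 or 1, got {self.label!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def centre(self) -> int:
        """1-based position of the central adenine (21 for a 41-nt window)."""
        return (len(self.seq) + 1) // 2


def read_fasta(path: PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, uppercased sequence), ...]``.

    Records are returned in file order.  Line wrapping and both Unix and
    Windows line endings are accepted.  An empty file yields an empty
    list.  A structurally malformed file (sequence data before the first
    header, or a header with no sequence) raises
    :class:`FastaFormatError` naming the offending line.
    """
    path = Path(path)
    text = path.read_text()
    _check_fasta_structure(text, str(path))
    records = SeqIO.parse(io.StringIO(text), "fasta")
    return [(rec.id, str(rec.seq).upper()) for rec in records]


def _check_fasta_structure(text: str, name: str) -> None:
    header_line: Optional[int] = None
    have_seq = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            if header_line is not None and not have_seq:
                raise FastaFormatError(
                    f"{name}: record starting at line {header_line} has no sequence"
                )
            if stripped == ">":
                raise FastaFormatError(f"{name}: empty header at line {lineno}")
            header_line = lineno
            have_seq = False
        else:
            if header_line is None:
                raise FastaFormatError(
                    f"{name}: sequence data before any header at line {lineno}"
                )
            have_seq = True
    if header_line is not None and not have_seq:
        raise FastaFormatError(
            f"{name}: record starting at line {header_line} has no sequence"
        )


def write_fasta(windows: Iterable[SampleWindow], path: PathLike, width: int = 60) -> None:
    """Write windows to FASTA in input order with fixed line wrapping."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.id}\n")
            for i in range(0, len(w.seq), width):
                fh.write(w.seq[i : i + width] + "\n")


def extract_windows(
    seq: str,
    flank: int = DEFAULT_FLANK,
    id_prefix: str = "win",
) -> list[SampleWindow]:
    """Extract one window per eligible adenine in ``seq``.

    An adenine at 1-based position ``p`` is eligible when
    ``flank < p <= len(seq) - flank``; adenines too close to either end
    are silently skipped.  The emitted window is
    ``seq[p - flank .. p + flank]`` (1-based, closed) with
    ``source_pos = p``.
    """
    if flank < 1:
        raise ValueError(f"flank must be >= 1, got {flank}")
    seq = _normalize(seq)
    out: list[SampleWindow] = []
    for i, base in enumerate(seq):  # i is 0-based, p = i + 1
        p = i + 1
        if base != "A" or p <= flank or p > len(seq) - flank:
            continue
        window = seq[i - flank : i + flank + 1]
        out.append(SampleWindow(id=f"{id_prefix}_{p}", seq=window, source_pos=p))
    return out


def read_labelled_table(path: PathLike) -> list[SampleWindow]:
    """Read a delimited table with header ``id, sequence, label``.

    The delimiter (comma or tab) is sniffed from the header line.
    Every row is validated against the :class:`SampleWindow` invariants;
    violations raise :class:`TableFormatError` naming the row.
    """
    import pandas as pd

    path = Path(path)
    header = ""
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line
                break
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    required = {"id", "sequence", "label"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(
            f"{path}: missing required column(s) {sorted(missing)}"
        )
    windows: list[SampleWindow] = []
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        raw_label = str(row.label).strip()
        if raw_label not in ("0", "1"):
            raise TableFormatError(
                f"{path}, row {row_num}: label {raw_label!r} not in {{0, 1}}"
            )
        try:
            windows.append(
                SampleWindow(id=str(row.id), seq=str(row.sequence), label=int(raw_label))
            )
        except ValueError as exc:
            raise TableFormatError(f"{path}, row {row_num}: {exc}") from exc
    return windows


def write_labelled_table(
    windows: Sequence[SampleWindow],
    path: PathLike,
    sep: str = "\t",
    header_comments: Optional[dict] = None,
) -> None:
    """Write windows as a delimited ``id, sequence, label`` table.

    ``header_comments`` entries are emitted as ``# key=value`` lines
    above the header for provenance.
    """
    with open(path, "w") as fh:
        for key, value in (header_comments or {}).items():
            fh.write(f"# {key}={value}\n")
        fh.write(sep.join(("id", "sequence", "label")) + "\n")
        for w in windows:
            label = "" if w.label is None else str(w.label)
            fh.write(sep.join((w.id, w.seq, label)) + "\n")
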