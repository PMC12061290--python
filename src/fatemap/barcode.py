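"""Combinatorial split-pool barcode architecture and whitelists.

The Microwell scATAC assay identifies a nucleus by a 28-bp prefix on the
barcode-bearing mate: three 6-bp bead-round segments followed by one 10-bp
Tn5-plate segment.  Each segment has its own whitelist of legal sequences;
whether a whitelist supports unambiguous one-mismatch correction is governed
by its minimum pairwise Hamming distance (>= 3 guarantees uniqueness).

This module only represents the layout and measures correction capacity;
the correction policy itself lives in :mod:`fatemap.demux`.
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

DNA_ALPHABET = frozenset("ACGT")

#: Separator used to join corrected segments into the canonical cell barcode.
BARCODE_JOIN = "+"


class WhitelistFormatError(ValueError):
    """A whitelist file violates the declared segment length or alphabet."""


@dataclass(frozen=True)
class Segment:
    """One contiguous barcode segment within the read prefix."""

    name: str
    length: int
    source: str  # bead-round-1 | bead-round-2 | bead-round-3 | tn5-plate

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"segment {self.name!r}: length must be positive")


@dataclass(frozen=True)
class ReadStructure:
    """Ordered, contiguous segment layout starting at position 0 of the barcode read.

    The default layout is three 6-bp bead segments followed by a 10-bp Tn5
    segment (28 bp total).  The Tn5 segment position is configurable by
    passing a different segment order.
    """

    segments: tuple[Segment, ...]
    barcode_read: int = 1  # which mate carries the prefix (1 or 2)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("structure needs at least one segment")
        if self.barcode_read not in (1, 2):
            raise ValueError("barcode_read must be 1 or 2")

    @property
    def total_prefix_length(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def offsets(self) -> tuple[tuple[int, int], ...]:
        """(start, end) slice per segment, contiguous from 0."""
        out, pos = [], 0
        for s in self.segments:
            out.append((pos, pos + s.length))
            pos += s.length
        return tuple(out)

    @classmethod
    def default(cls) -> "ReadStructure":
        return cls(
            segments=(
                Segment("bc1", 6, "bead-round-1"),
                Segment("bc2", 6, "bead-round-2"),
                Segment("bc3", 6, "bead-round-3"),
                Segment("tn5", 10, "tn5-plate"),
            )
        )


def min_pairwise_hamming(seqs: Sequence[str]) -> float:
    """Exact minimum Hamming distance over all unordered pairs.

    Returns ``math.inf`` for fewer than two sequences (degenerate sets place
    no constraint on correction).
    """
    if len(seqs) < 2:
        return math.inf
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must share one length")
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    best = arr.shape[1]
    for i in range(len(seqs) - 1):
        d = (arr[i + 1 :] != arr[i]).sum(axis=1).min()
        if d < best:
            best = int(d)
            if best == 1:
                break
    return best


@dataclass
class Whitelist:
    """Per-segment legal sequence sets with their minimum pairwise distances."""

    sequences: dict[str, tuple[str, ...]]  # segment name -> sequences
    min_distance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.min_distance:
            self.min_distance = {
                name: min_pairwise_hamming(seqs) for name, seqs in self.sequences.items()
            }

    @property
    def supports_one_mismatch(self) -> bool:
        """True when every segment's minimum distance >= 3 (unique 1-mismatch rescue)."""
        return all(d >= 3 for d in self.min_distance.values())


@dataclass(frozen=True)
class CellBarcode:
    """Canonical corrected cell identifier: segments joined with '+', in read order."""

    segments: tuple[str, ...]

    @property
    def identifier(self) -> str:
        return BARCODE_JOIN.join(self.segments)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.identifier


def _read_segment_file(path: Path, expected_length: int) -> tuple[str, ...]:
    opener = gzip.open if str(path).endswith(".gz") else open
    seqs: list[str] = []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            seq = line.strip()
            if not seq:
                continue
            if len(seq) != expected_length:
                raise WhitelistFormatError(
                    f"{path}:{lineno}: sequence {seq!r} has length {len(seq)}, "
                    f"expected {expected_length}"
                )
            if not set(seq) <= DNA_ALPHABET:
                raise WhitelistFormatError(
                    f"{path}:{lineno}: sequence {seq!r} contains non-ACGT characters"
                )
            seqs.append(seq)
    if not seqs:
        raise WhitelistFormatError(f"{path}: empty whitelist file")
    if len(set(seqs)) != len(seqs):
        raise WhitelistFormatError(f"{path}: duplicate sequences in segment whitelist")
    return tuple(seqs)


def build_whitelist(
    segment_files: Sequence[str | Path], structure: ReadStructure
) -> Whitelist:
    """Load one plain-text whitelist file per segment and measure correction capacity.

    Emits a ``UserWarning`` when any segment's minimum pairwise Hamming
    distance is below 3, in which case one-mismatch correction is not
    guaranteed unambiguous (ambiguity handling is delegated to demux).
    """
    if len(segment_files) != len(structure.segments):
        raise ValueError(
            f"{len(segment_files)} files for {len(structure.segments)} segments"
        )
    sequences = {
        seg.name: _read_segment_file(Path(f), seg.length)
        for seg, f in zip(structure.segments, segment_files)
    }
    wl = Whitelist(sequences=sequences)
    for name, d in wl.min_distance.items():
        if d < 3:
            warnings.warn(
                f"segment {name!r}: minimum pairwise Hamming distance {d} < 3; "
                "one-mismatch correction is not guaranteed unambiguous",
                UserWarning,
                stacklevel=2,
            )
    return wl
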