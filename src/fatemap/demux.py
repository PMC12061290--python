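"""Barcode extraction, quality gating, whitelist correction, and trimming.

Pipeline per read pair: slice the 28-bp prefix into segments, gate on
barcode base quality (< Q10 removed), correct each segment independently
against its whitelist allowing one mismatch, then emit the mate with the
prefix trimmed and the canonical cell barcode embedded in the read name.
Ambiguous corrections (two whitelist entries at distance 1) are rejected,
never tie-broken.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pysam

from .barcode import CellBarcode, ReadStructure, Whitelist
from .io import open_text_writer

REJECT_TOO_SHORT = "too-short"
REJECT_QUALITY = "rejected-quality"
REJECT_UNCORRECTABLE = "rejected-uncorrectable"
REJECT_AMBIGUOUS = "rejected-ambiguous"

_AMBIGUOUS = object()  # sentinel in the neighbor lookup table


class DesynchronizedMatesError(RuntimeError):
    pass


@dataclass
class BarcodeObservation:
    """Raw prefix segments plus the genomic remainder of the barcode read."""

    segments: tuple[str, ...]
    segment_quals: tuple[bytes, ...]  # raw Phred values, one byte per base
    remainder_seq: str
    remainder_qual: str  # Phred+33 encoded

    @property
    def min_quality(self) -> int:
        return min(min(q) for q in self.segment_quals)

    @property
    def mean_quality(self) -> float:
        flat = b"".join(self.segment_quals)
        return sum(flat) / len(flat)


@dataclass
class DemuxStats:
    """Read accounting; rejection categories partition the input count."""

    total: int = 0
    rejected_too_short: int = 0
    rejected_quality: int = 0
    rejected_uncorrectable: int = 0
    rejected_ambiguous: int = 0
    assigned: int = 0
    corrections_per_segment: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        categories = (
            self.assigned
            + self.rejected_too_short
            + self.rejected_quality
            + self.rejected_uncorrectable
            + self.rejected_ambiguous
        )
        if categories != self.total:
            raise AssertionError(
                f"stats do not reconcile: total={self.total}, categories={categories}"
            )

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "rejected_too_short": self.rejected_too_short,
            "rejected_quality": self.rejected_quality,
            "rejected_uncorrectable": self.rejected_uncorrectable,
            "rejected_ambiguous": self.rejected_ambiguous,
            "assigned": self.assigned,
            "corrections_per_segment": dict(self.corrections_per_segment),
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def write_tsv(self, path: str | Path) -> None:
        d = self.to_dict()
        segs = d.pop("corrections_per_segment")
        lines = [f"{k}\t{v}" for k, v in d.items()]
        lines += [f"corrected_{k}\t{v}" for k, v in segs.items()]
        Path(path).write_text("\n".join(lines) + "\n")


def parse_read(seq: str, qual: str, structure: ReadStructure) -> BarcodeObservation | None:
    """Slice the prefix at the declared offsets; ``None`` marks a too-short read."""
    if len(seq) < structure.total_prefix_length:
        return None
    phred = bytes(ord(c) - 33 for c in qual[: structure.total_prefix_length])
    segs, quals = [], []
    for start, end in structure.offsets:
        segs.append(seq[start:end])
        quals.append(phred[start:end])
    n = structure.total_prefix_length
    return BarcodeObservation(
        segments=tuple(segs),
        segment_quals=tuple(quals),
        remainder_seq=seq[n:],
        remainder_qual=qual[n:],
    )


def passes_quality(
    obs: BarcodeObservation, min_q: int = 10, mode: str = "min"
) -> bool:
    """Quality gate over the 28 barcode bases.

    ``mode='min'`` (default, strictest reading of the < Q10 removal rule)
    requires every barcode base >= ``min_q``; ``mode='mean'`` requires the
    mean base quality >= ``min_q``.  A score exactly at the threshold passes.
    """
    if not obs.segment_quals or any(len(q) == 0 for q in obs.segment_quals):
        raise ValueError("missing barcode base qualities (malformed FASTQ)")
    if mode == "min":
        return obs.min_quality >= min_q
    if mode == "mean":
        return obs.mean_quality >= min_q
    raise ValueError(f"unknown quality mode {mode!r}")


def _neighbors(seq: str) -> Iterator[str]:
    for i, base in enumerate(seq):
        for alt in "ACGT":
            if alt != base:
                yield seq[:i] + alt + seq[i + 1 :]


class SegmentCorrector:
    """O(1) per-segment correction via a precomputed distance-<=1 lookup table."""

    def __init__(self, sequences: tuple[str, ...]):
        self.exact = frozenset(sequences)
        table: dict[str, object] = {}
        for entry in sequences:
            for nb in _neighbors(entry):
                table[nb] = _AMBIGUOUS if nb in table else entry
        self.near: dict[str, object] = table

    def correct(self, observed: str) -> tuple[str | None, str | None]:
        """Returns (corrected sequence, rejection category)."""
        if observed in self.exact:
            return observed, None
        hit = self.near.get(observed)
        if hit is None:
            return None, REJECT_UNCORRECTABLE
        if hit is _AMBIGUOUS:
            return None, REJECT_AMBIGUOUS
        return hit, None  # type: ignore[return-value]


def build_correctors(wl: Whitelist, structure: ReadStructure) -> dict[str, SegmentCorrector]:
    return {
        seg.name: SegmentCorrector(wl.sequences[seg.name]) for seg in structure.segments
    }


def correct_barcode(
    obs: BarcodeObservation,
    wl: Whitelist,
    structure: ReadStructure | None = None,
    correctors: dict[str, SegmentCorrector] | None = None,
) -> tuple[CellBarcode | None, str | None, list[str]]:
    """Correct all segments independently; every segment must resolve.

    Returns (barcode or None, rejection category or None, names of segments
    that required a one-mismatch correction).
    """
    structure = structure or ReadStructure.default()
    if correctors is None:
        correctors = build_correctors(wl, structure)
    out, corrected_names = [], []
    for seg, observed in zip(structure.segments, obs.segments):
        fixed, reject = correctors[seg.name].correct(observed)
        if reject is not None:
            return None, reject, corrected_names
        if fixed != observed:
            corrected_names.append(seg.name)
        out.append(fixed)
    return CellBarcode(tuple(out)), None, corrected_names


def _fastq_records(path: str | Path) -> Iterator[tuple[str, str, str]]:
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            if rec.quality is None:
                raise ValueError(f"{path}: record {rec.name} has no qualities")
            yield rec.name, rec.sequence, rec.quality


def _open_out(path: str | Path):
    return open_text_writer(path)


def demux_fastq(
    r1: str | Path,
    r2: str | Path,
    wl: Whitelist,
    structure: ReadStructure | None = None,
    min_q: int = 10,
    quality_mode: str = "min",
    out_r1: str | Path | None = None,
    out_r2: str | Path | None = None,
    name_separator: str = ":",
) -> tuple[DemuxStats, list[tuple[str, str]]]:
    """Demultiplex a synchronized FASTQ pair.

    The barcode prefix resides on read 1 unless the structure says otherwise.
    Assigned reads are written with the prefix trimmed from the barcode mate
    and the read name rewritten as ``<barcode><sep><original name>``.

    Returns the stats and an in-memory list of (read name, barcode
    identifier) assignments for downstream truth-table comparison.
    """
    structure = structure or ReadStructure.default()
    correctors = build_correctors(wl, structure)
    stats = DemuxStats(
        corrections_per_segment={s.name: 0 for s in structure.segments}
    )
    assignments: list[tuple[str, str]] = []

    out1 = _open_out(out_r1) if out_r1 is not None else None
    out2 = _open_out(out_r2) if out_r2 is not None else None
    try:
        it1, it2 = _fastq_records(r1), _fastq_records(r2)
        for (name1, seq1, qual1), (name2, seq2, qual2) in zip(it1, it2, strict=True):
            if name1.split("/")[0] != name2.split("/")[0]:
                raise DesynchronizedMatesError(
                    f"mate names disagree: {name1!r} vs {name2!r}"
                )
            stats.total += 1
            if structure.barcode_read == 1:
                bseq, bqual, oseq, oqual = seq1, qual1, seq2, qual2
            else:
                bseq, bqual, oseq, oqual = seq2, qual2, seq1, qual1
            obs = parse_read(bseq, bqual, structure)
            if obs is None:
                stats.rejected_too_short += 1
                continue
            if not passes_quality(obs, min_q=min_q, mode=quality_mode):
                stats.rejected_quality += 1
                continue
            barcode, reject, corrected = correct_barcode(
                obs, wl, structure, correctors
            )
            if reject == REJECT_UNCORRECTABLE:
                stats.rejected_uncorrectable += 1
                continue
            if reject == REJECT_AMBIGUOUS:
                stats.rejected_ambiguous += 1
                continue
            assert barcode is not None
            stats.assigned += 1
            for nm in corrected:
                stats.corrections_per_segment[nm] += 1
            tagged = f"{barcode.identifier}{name_separator}{name1}"
            assignments.append((name1, barcode.identifier))
            if out1 is not None and out2 is not None:
                if structure.barcode_read == 1:
                    out1.write(f"@{tagged}\n{obs.remainder_seq}\n+\n{obs.remainder_qual}\n")
                    out2.write(f"@{tagged}\n{oseq}\n+\n{oqual}\n")
                else:
                    out1.write(f"@{tagged}\n{oseq}\n+\n{oqual}\n")
                    out2.write(f"@{tagged}\n{obs.remainder_seq}\n+\n{obs.remainder_qual}\n")
    finally:
        if out1 is not None:
            out1.close()
        if out2 is not None:
            out2.close()
    stats.check()
    return stats, assignments


def barcode_from_read_name(name: str, separator: str = ":") -> str:
    """Recover the canonical barcode embedded by :func:`demux_fastq`."""
    return name.split(separator, 1)[0]
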