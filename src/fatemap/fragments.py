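"""Tn5 fragments: insertion-shift correction, dedup, and per-cell scATAC QC.

Tagmentation duplicates 9 bp at each insertion, so plus-strand insertions
are shifted by +4 and minus-strand insertions by -5: a raw template
[start, end) becomes [start + 4, end - 5).  Fragments on chrY and chrM are
excluded by default, exact duplicates (chrom, start, end, barcode) collapse
to one row with a count, and per-cell quality is the TSS enrichment score
(fold concentration of insertions at transcription start sites over flank
background) together with the unique-fragment count.  Cells pass QC with
TSS score > 10 and unique fragments > 1500 (both strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "count"]
DEFAULT_EXCLUDED = ("chrY", "chrM")
CHROM_ALIASES = {"chrm": {"chrm", "mt", "chrmt", "m"}, "chry": {"chry", "y"}}


@dataclass
class PairCounters:
    """Accounting for alignment pairs that never become fragments."""

    pairs_in: int = 0
    missing_barcode: int = 0
    improper_or_unmapped: int = 0
    low_mapq: int = 0
    empty_after_shift: int = 0
    excluded_chrom: int = 0
    fragments_out: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def shift_insertions(start: int, end: int) -> tuple[int, int] | None:
    """Apply the +4/-5 Tn5 correction to a raw template interval.

    Returns the corrected half-open interval, or ``None`` when the raw
    template is shorter than 9 bp and the corrected interval is empty.
    """
    s, e = start + 4, end - 5
    if s >= e:
        return None
    return s, e


def _excluded_names(excluded: tuple[str, ...]) -> set[str]:
    out: set[str] = set()
    for name in excluded:
        low = name.lower()
        out.add(low)
        for canon, aliases in CHROM_ALIASES.items():
            if low in aliases or low == canon:
                out |= aliases
    return out


def iter_template_intervals(
    path: str | Path,
    min_mapq: int = 2,
    barcode_tag: str = "CB",
    name_separator: str = ":",
    counters: PairCounters | None = None,
):
    """Yield (chrom, raw_start, raw_end, barcode) per properly-paired template.

    Each template is taken once, from the leftmost mate (positive template
    length).  The barcode comes from the tag when present, else from the
    read-name prefix written by demux.
    """
    counters = counters if counters is not None else PairCounters()
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for read in fh:
            if read.is_read2 or read.is_secondary or read.is_supplementary:
                continue
            counters.pairs_in += 1
            if (
                read.is_unmapped
                or read.mate_is_unmapped
                or not read.is_proper_pair
                or read.reference_name != read.next_reference_name
            ):
                counters.improper_or_unmapped += 1
                continue
            if read.mapping_quality < min_mapq:
                counters.low_mapq += 1
                continue
            if read.has_tag(barcode_tag):
                barcode = read.get_tag(barcode_tag)
            elif name_separator in (read.query_name or ""):
                barcode = read.query_name.split(name_separator, 1)[0]
            else:
                counters.missing_barcode += 1
                continue
            tlen = read.template_length
            if tlen > 0:
                start = read.reference_start
                end = start + tlen
            else:
                end = read.reference_end if read.reference_end is not None else 0
                start = end + tlen  # tlen < 0
            if start >= end:
                counters.improper_or_unmapped += 1
                continue
            yield read.reference_name, start, end, barcode


@dataclass
class FragmentTable:
    """Shifted, deduplicated, coordinate-sorted per-cell fragments."""

    df: pd.DataFrame
    counters: PairCounters = field(default_factory=PairCounters)

    def __post_init__(self) -> None:
        if list(self.df.columns) != FRAGMENT_COLUMNS:
            raise ValueError(f"expected columns {FRAGMENT_COLUMNS}")

    def unique_fragments_per_cell(self) -> pd.Series:
        return self.df.groupby("barcode", sort=True).size()

    def write(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def read(cls, path: str | Path) -> "FragmentTable":
        df = pd.read_csv(path, sep="\t", header=None, names=FRAGMENT_COLUMNS)
        return cls(df=df)


def build_fragments(
    alignments: str | Path | list[tuple[str, int, int, str]],
    excluded_chroms: tuple[str, ...] = DEFAULT_EXCLUDED,
    known_chroms: dict[str, int] | None = None,
    min_mapq: int = 2,
    barcode_tag: str = "CB",
) -> FragmentTable:
    """Shift, filter, deduplicate, and sort templates into a fragment table.

    ``alignments`` is a SAM/BAM path or an already-extracted list of raw
    (chrom, start, end, barcode) template intervals.
    """
    counters = PairCounters()
    if isinstance(alignments, (str, Path)):
        records = iter_template_intervals(
            alignments, min_mapq=min_mapq, barcode_tag=barcode_tag, counters=counters
        )
    else:
        records = iter(alignments)
        counters.pairs_in = len(alignments)

    excluded = _excluded_names(tuple(excluded_chroms))
    rows = []
    unknown: set[str] = set()
    for chrom, start, end, barcode in records:
        if known_chroms is not None and chrom not in known_chroms:
            unknown.add(chrom)
            continue
        if chrom.lower() in excluded:
            counters.excluded_chrom += 1
            continue
        shifted = shift_insertions(start, end)
        if shifted is None:
            counters.empty_after_shift += 1
            continue
        rows.append((chrom, shifted[0], shifted[1], barcode))
    if unknown:
        raise ValueError(f"unknown chromosome names: {sorted(unknown)}")

    df = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS[:4])
    if len(df):
        df = (
            df.groupby(FRAGMENT_COLUMNS[:4], sort=False, as_index=False)
            .size()
            .rename(columns={"size": "count"})
            .sort_values(FRAGMENT_COLUMNS[:4], kind="mergesort", ignore_index=True)
        )
    else:
        df["count"] = pd.Series(dtype=int)
    counters.fragments_out = len(df)
    return FragmentTable(df=df, counters=counters)


def read_tss_bed(path: str | Path) -> pd.DataFrame:
    """Read TSS sites from BED (3+ columns; strand from column 6 when present)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = pd.DataFrame({"chrom": df[0], "pos": df[1].astype(int)})
    out["strand"] = df[5] if df.shape[1] >= 6 else "+"
    return out


@dataclass
class CellQC:
    """Per-cell scATAC QC: unique fragments, TSS enrichment, pass flag."""

    table: pd.DataFrame  # index barcode; columns n_fragments, tss_score, flag_no_fragments

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")


def tss_enrichment(
    fragments: FragmentTable,
    tss: pd.DataFrame,
    flank: int = 2000,
    window: int = 101,
    background_edge: int = 100,
    background_floor: float = 0.1,
) -> pd.Series:
    """Per-cell TSS enrichment: central-window fold over outer-flank background.

    Both fragment ends are insertion sites.  Sites within +-``flank`` of any
    TSS are binned by strand-oriented offset; the score is the mean count in
    the central ``window`` bases divided by the mean count in the outermost
    ``background_edge`` bases of each flank (floored at ``background_floor``).
    Cells with zero fragments score 0.
    """
    if len(tss) == 0:
        raise ValueError("need at least one TSS site")
    width = 2 * flank + 1
    cells = fragments.df["barcode"].unique()
    profiles = {c: np.zeros(width) for c in cells}

    for chrom, grp in fragments.df.groupby("chrom", sort=False):
        sites_chrom = tss[tss["chrom"] == chrom]
        if len(sites_chrom) == 0:
            continue
        # insertion sites: left cut at start, right cut at end - 1
        pos = np.concatenate([grp["start"].to_numpy(), grp["end"].to_numpy() - 1])
        cell = np.concatenate([grp["barcode"].to_numpy()] * 2)
        order = np.argsort(pos, kind="mergesort")
        pos, cell = pos[order], cell[order]
        for _, site in sites_chrom.iterrows():
            lo = np.searchsorted(pos, site["pos"] - flank, side="left")
            hi = np.searchsorted(pos, site["pos"] + flank, side="right")
            if lo == hi:
                continue
            offsets = pos[lo:hi] - site["pos"]
            if site["strand"] == "-":
                offsets = -offsets
            idx = offsets + flank
            for c, i in zip(cell[lo:hi], idx):
                profiles[c][i] += 1

    half = window // 2
    center = slice(flank - half, flank + half + 1)
    scores = {}
    for c, prof in profiles.items():
        background = np.concatenate(
            [prof[:background_edge], prof[-background_edge:]]
        ).mean()
        scores[c] = prof[center].mean() / max(background, background_floor)
    return pd.Series(scores, name="tss_score", dtype=float)


def compute_cell_qc(
    fragments: FragmentTable,
    tss: pd.DataFrame,
    flank: int = 2000,
    window: int = 101,
    barcodes: list[str] | None = None,
) -> CellQC:
    """Per-cell QC table; ``barcodes`` adds expected cells that may have zero
    fragments (scored 0 and flagged)."""
    n_frag = fragments.unique_fragments_per_cell().rename("n_fragments")
    scores = tss_enrichment(fragments, tss, flank=flank, window=window)
    table = pd.concat([n_frag, scores], axis=1)
    if barcodes is not None:
        table = table.reindex(table.index.union(pd.Index(barcodes)))
    table = table.fillna(0)
    table["n_fragments"] = table["n_fragments"].astype(int)
    table["flag_no_fragments"] = table["n_fragments"] == 0
    table.index.name = "barcode"
    return CellQC(table=table)


def filter_cells(
    qc: CellQC, tss_min: float = 10.0, frag_min: int = 1500
) -> list[str]:
    """Barcodes with TSS score > tss_min AND unique fragments > frag_min (strict)."""
    t = qc.table
    mask = (t["tss_score"] > tss_min) & (t["n_fragments"] > frag_min)
    return sorted(t.index[mask])
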