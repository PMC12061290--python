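"""Synthetic inputs with ground truth for every toolkit stage.

Emulates, at desk scale, the structures the toolkit consumes: combinatorial
barcoded read pairs with per-base substitution errors, toy paired
alignments with known Tn5 insertion intervals and planted duplicates, and a
multi-timepoint expression count matrix with planted lineage branching,
driver genes, a high-connectome-degree (high-potency) population, and
pulsing cell-cycle / ribosomal-protein modules.  Every output is fully
determined by the seed and is accompanied by a truth table.

The generative model is a stand-in, not a fit to real data: negative
binomial counts (gamma-Poisson, dispersion 0.1) around branch-specific
log-mean programs drifting along the lineage tree; no doublets, ambient
RNA, indels, or quality ramps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .barcode import ReadStructure, Whitelist
from .io import open_text_writer

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Stated world for all three generators; the seed determines everything."""

    seed: int = 0
    # reads
    n_cells: int = 200
    n_read_pairs: int = 10_000
    error_rate: float = 0.001
    read_length: int = 50          # barcode read: 28 bp prefix + genomic insert
    whitelist_sizes: tuple[int, ...] = (24, 24, 24, 96)
    min_whitelist_distance: int = 3
    # alignments
    chrom_lengths: dict = field(default_factory=lambda: {
        "chr1": 400_000, "chr2": 400_000, "chrY": 60_000, "chrM": 16_000,
    })
    tss_per_chrom: int = 20
    n_good_cells: int = 6
    n_background_cells: int = 6
    fragments_per_good_cell: int = 2500
    fragments_per_background_cell: int = 300
    tss_fraction: float = 0.9      # good-cell fragments starting at a TSS
    duplicate_rate: float = 0.0
    # timecourse
    timepoints: tuple[str, ...] = ("D0", "D6", "D12", "D35")
    cells_per_timepoint: int = 500
    n_genes: int = 600
    branch_timepoint_index: int = 1    # branches separate at this timepoint
    n_driver_genes: int = 40           # per branch
    drift: float = 1.0                 # log-mean increment per stage on drivers
    n_hub_genes: int = 50              # high-connectome-degree module
    hub_boost: float = 1.5             # log-mean boost in the high-potency cells
    hub_cell_fraction: float = 0.25
    n_rp_genes: int = 20
    n_cc_genes: int = 20
    n_mito_genes: int = 5
    module_boost: float = 1.0          # RP / cell-cycle pulse amplitude
    library_size: int = 3000
    dispersion: float = 0.1            # NB dispersion (var = mu + dispersion * mu^2)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key in ("whitelist_sizes", "timepoints"):
            if key in known:
                known[key] = tuple(known[key])
        return cls(**known)


@dataclass
class TruthTable:
    """Ground truth covering every emitted record."""

    read_barcodes: pd.DataFrame | None = None      # read name -> true barcode
    cell_labels: pd.DataFrame | None = None        # barcode -> good/background, counts
    fragment_counts: pd.Series | None = None       # barcode -> true unique fragments
    cell_meta: pd.DataFrame | None = None          # barcode -> timepoint/branch/...
    gene_sets: dict = field(default_factory=dict)  # planted gene lists


# ---------------------------------------------------------------------------
# whitelists and reads

def simulate_whitelists(
    config: SimConfig, structure: ReadStructure | None = None
) -> Whitelist:
    """Rejection-sample per-segment whitelists at pairwise Hamming >= 3."""
    structure = structure or ReadStructure.default()
    rng = np.random.default_rng(config.seed)
    if len(config.whitelist_sizes) != len(structure.segments):
        raise ValueError("one whitelist size per segment required")
    sequences = {}
    for seg, target in zip(structure.segments, config.whitelist_sizes):
        if target < 2:
            raise ValueError(f"segment {seg.name}: whitelist size must be >= 2")
        accepted: list[np.ndarray] = []
        stall = 0
        while len(accepted) < target:
            stall += 1
            if stall > 5000:  # no acceptance in 5000 draws: floor unreachable
                raise ValueError(
                    f"segment {seg.name}: cannot reach {target} sequences of "
                    f"length {seg.length} at Hamming floor "
                    f"{config.min_whitelist_distance}"
                )
            cand = rng.integers(0, 4, size=seg.length)
            if all(
                (cand != prev).sum() >= config.min_whitelist_distance
                for prev in accepted
            ):
                accepted.append(cand)
                stall = 0
        sequences[seg.name] = tuple(
            _BASES[a].tobytes().decode() for a in accepted
        )
    wl = Whitelist(sequences=sequences)
    assert all(
        d >= config.min_whitelist_distance for d in wl.min_distance.values()
    )
    return wl


def simulate_reads(
    config: SimConfig,
    out_r1: str | Path | None = None,
    out_r2: str | Path | None = None,
    whitelist: Whitelist | None = None,
    structure: ReadStructure | None = None,
) -> tuple[Whitelist, TruthTable, list[str], list[str]]:
    """Barcoded FASTQ pair: 28-bp whitelist prefix + genomic insert, with
    seeded substitution errors.

    Errored bases get Q14 and error-free bases Q37, so errored barcodes
    still pass the Q10 gate and exercise the one-mismatch rescue.  Returns
    (whitelist, truth, r1 records, r2 records); the record lists hold
    4-line FASTQ blocks and are also written to ``out_r1``/``out_r2`` when
    given.
    """
    structure = structure or ReadStructure.default()
    wl = whitelist or simulate_whitelists(config, structure)
    rng = np.random.default_rng(config.seed + 1)
    prefix_len = structure.total_prefix_length
    if config.read_length < prefix_len:
        raise ValueError("read_length shorter than the barcode prefix")

    # sample distinct cells from the whitelist product set
    seg_names = [s.name for s in structure.segments]
    combos = rng.integers(
        0, [len(wl.sequences[n]) for n in seg_names],
        size=(config.n_cells * 3, len(seg_names)),
    )
    combos = np.unique(combos, axis=0)
    rng.shuffle(combos)
    combos = combos[: config.n_cells]
    if len(combos) < config.n_cells:
        raise ValueError("whitelist product set too small for n_cells")
    cell_barcodes = [
        "+".join(wl.sequences[n][i] for n, i in zip(seg_names, row))
        for row in combos
    ]

    n = config.n_read_pairs
    cell_idx = rng.integers(0, config.n_cells, size=n)
    prefix_bytes = np.frombuffer(
        "".join(b.replace("+", "") for b in cell_barcodes).encode(), dtype=np.uint8
    ).reshape(config.n_cells, prefix_len)

    r1 = np.empty((n, config.read_length), dtype=np.uint8)
    r1[:, :prefix_len] = prefix_bytes[cell_idx]
    insert_len = config.read_length - prefix_len
    r1[:, prefix_len:] = _BASES[rng.integers(0, 4, size=(n, insert_len))]
    r2 = _BASES[rng.integers(0, 4, size=(n, config.read_length))]

    def inject(reads: np.ndarray) -> np.ndarray:
        err = rng.random(reads.shape) < config.error_rate
        shifted = reads.copy()
        # substitute with a different base: rotate 1-3 steps in ACGT order
        rot = rng.integers(1, 4, size=int(err.sum()))
        base_idx = np.searchsorted(_BASES, reads[err])
        shifted[err] = _BASES[(base_idx + rot) % 4]
        return shifted, err

    r1, err1 = inject(r1)
    r2, err2 = inject(r2)
    q1 = np.where(err1, ord("/"), ord("F")).astype(np.uint8)  # Q14 / Q37
    q2 = np.where(err2, ord("/"), ord("F")).astype(np.uint8)

    names = [f"read{i:07d}" for i in range(n)]
    rec1 = [
        f"@{nm}\n{bytes(r1[i]).decode()}\n+\n{bytes(q1[i]).decode()}"
        for i, nm in enumerate(names)
    ]
    rec2 = [
        f"@{nm}\n{bytes(r2[i]).decode()}\n+\n{bytes(q2[i]).decode()}"
        for i, nm in enumerate(names)
    ]
    for path, recs in ((out_r1, rec1), (out_r2, rec2)):
        if path is not None:
            with open_text_writer(path) as fh:
                fh.write("\n".join(recs) + "\n")

    truth = TruthTable(
        read_barcodes=pd.DataFrame(
            {"read": names, "barcode": [cell_barcodes[i] for i in cell_idx],
             "barcode_errors": err1[:, :prefix_len].sum(axis=1)}
        ).set_index("read")
    )
    return wl, truth, rec1, rec2


# ---------------------------------------------------------------------------
# alignments

def tss_sites(config: SimConfig) -> pd.DataFrame:
    """Evenly spaced TSS sites on the non-excluded chromosomes, BED-like."""
    rows = []
    for chrom, length in config.chrom_lengths.items():
        if chrom.lower() in {"chry", "chrm"}:
            continue
        step = length // (config.tss_per_chrom + 1)
        for k in range(1, config.tss_per_chrom + 1):
            rows.append({"chrom": chrom, "pos": k * step,
                         "strand": "+" if k % 2 else "-"})
    return pd.DataFrame(rows)


def write_tss_bed(tss: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, row in tss.iterrows():
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['pos'] + 1}\t"
                f"tss{i}\t0\t{row['strand']}\n"
            )


def simulate_alignments(
    config: SimConfig, out_sam: str | Path | None = None
) -> tuple[list[tuple], TruthTable, pd.DataFrame]:
    """Properly paired toy alignments with known Tn5 template intervals.

    Good cells concentrate fragment starts at TSS centers (sd 25 bp) and
    carry > 1500 unique fragments; background cells are uniform and sparse.
    Duplicate pairs are planted at ``duplicate_rate``.  A sprinkle of chrY
    and chrM fragments exercises the exclusion filter.  Returns the raw
    (chrom, start, end, barcode) truth records (pre-duplication), the truth
    table, and the TSS table; optionally writes a coordinate-sorted SAM.
    """
    rng = np.random.default_rng(config.seed + 2)
    tss = tss_sites(config)
    main_chroms = [c for c in config.chrom_lengths if c.lower() not in {"chry", "chrm"}]

    cells = (
        [f"GOOD{i:02d}" for i in range(config.n_good_cells)]
        + [f"BKGD{i:02d}" for i in range(config.n_background_cells)]
    )
    labels = ["good"] * config.n_good_cells + ["background"] * config.n_background_cells

    tss_pos = {
        c: tss.loc[tss["chrom"] == c, "pos"].to_numpy() for c in main_chroms
    }
    records: list[tuple] = []   # unique fragments (chrom, start, end, barcode)
    for cell, label in zip(cells, labels):
        n_frag = (
            config.fragments_per_good_cell
            if label == "good"
            else config.fragments_per_background_cell
        )
        seen = set()
        while len(seen) < n_frag:
            chrom = main_chroms[rng.integers(0, len(main_chroms))]
            length = int(rng.integers(150, 400))
            if label == "good" and rng.random() < config.tss_fraction:
                site = tss_pos[chrom][rng.integers(len(tss_pos[chrom]))]
                start = int(site + round(rng.normal(0, 25))) - 4
            else:
                start = int(rng.integers(0, config.chrom_lengths[chrom] - length))
            start = max(0, min(start, config.chrom_lengths[chrom] - length - 10))
            key = (chrom, start, start + length, cell)
            if key not in seen:
                seen.add(key)
        records.extend(sorted(seen))

    # a few excluded-chromosome fragments per cell
    for cell in cells:
        for chrom in ("chrY", "chrM"):
            if chrom in config.chrom_lengths:
                start = int(rng.integers(0, config.chrom_lengths[chrom] - 500))
                records.append((chrom, start, start + 200, cell))

    emitted = []
    for rec in records:
        emitted.append(rec)
        if rng.random() < config.duplicate_rate:
            emitted.append(rec)

    truth = TruthTable(
        cell_labels=pd.DataFrame({"barcode": cells, "label": labels}).set_index("barcode"),
        fragment_counts=pd.Series(
            {c: sum(1 for r in records if r[3] == c and r[0] not in ("chrY", "chrM"))
             for c in cells},
            name="unique_fragments",
        ),
    )

    if out_sam is not None:
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": ln} for c, ln in config.chrom_lengths.items()],
        }
        order = {c: i for i, c in enumerate(config.chrom_lengths)}
        emitted_sorted = sorted(emitted, key=lambda r: (order[r[0]], r[1], r[2], r[3]))
        read_len = 50
        with pysam.AlignmentFile(str(out_sam), "w", header=header) as fh:
            for i, (chrom, start, end, cell) in enumerate(emitted_sorted):
                tid = fh.get_tid(chrom)
                for is_r1 in (True, False):
                    a = pysam.AlignedSegment(fh.header)
                    a.query_name = f"frag{i:07d}"
                    a.reference_id = tid
                    a.next_reference_id = tid
                    a.mapping_quality = 60
                    a.cigarstring = f"{read_len}M"
                    a.query_sequence = "A" * read_len
                    a.query_qualities = pysam.qualitystring_to_array("F" * read_len)
                    a.set_tag("CB", cell)
                    if is_r1:
                        a.flag = 99
                        a.reference_start = start
                        a.next_reference_start = end - read_len
                        a.template_length = end - start
                    else:
                        a.flag = 147
                        a.reference_start = end - read_len
                        a.next_reference_start = start
                        a.template_length = -(end - start)
                    fh.write(a)
    return emitted, truth, tss


# ---------------------------------------------------------------------------
# timecourse

def simulate_timecourse(config: SimConfig):
    """Multi-timepoint NB counts with planted branching and modules.

    Returns (AnnData with counts and obs metadata, TruthTable, connectome
    edge-list DataFrame, homology-pairs DataFrame).

    The lineage is a single root splitting into branches A and B at
    ``branch_timepoint_index``; each branch's driver genes gain ``drift``
    in log-mean per stage after the split.  A ``hub_cell_fraction`` subset
    of cells (the metastable, high-potency population) over-expresses the
    hub genes of the toy connectome by ``hub_boost``.  RP genes pulse at
    the middle stage and cell-cycle genes at the first post-split stage.
    """
    import anndata as ad

    rng = np.random.default_rng(config.seed + 3)
    n_special = (
        config.n_driver_genes * 2 + config.n_hub_genes
        + config.n_rp_genes + config.n_cc_genes + config.n_mito_genes
    )
    if config.n_genes < n_special + 50:
        raise ValueError("n_genes too small for the planted modules")

    genes: list[str] = []
    drivers_a = [f"DrvA{i:03d}" for i in range(config.n_driver_genes)]
    drivers_b = [f"DrvB{i:03d}" for i in range(config.n_driver_genes)]
    hubs = [f"Hub{i:03d}" for i in range(config.n_hub_genes)]
    rp = [("Rps" if i % 2 else "Rpl") + f"{i:02d}" for i in range(config.n_rp_genes)]
    cc = [f"Ccnx{i:02d}" for i in range(config.n_cc_genes)]
    mito = [f"mt-Gene{i}" for i in range(config.n_mito_genes)]
    n_flat = config.n_genes - n_special
    flat = [f"Gene{i:04d}" for i in range(n_flat)]
    genes = drivers_a + drivers_b + hubs + rp + cc + mito + flat
    gidx = {g: i for i, g in enumerate(genes)}

    base_logmean = rng.normal(1.0, 0.5, size=config.n_genes)

    tps = list(config.timepoints)
    rows, obs_rows = [], []
    split = config.branch_timepoint_index
    mid_stage = min(split + 1, len(tps) - 1)
    for t_i, tp in enumerate(tps):
        for c in range(config.cells_per_timepoint):
            if t_i < split:
                branch = "root"
            else:
                branch = "A" if c < config.cells_per_timepoint // 2 else "B"
            hub_cell = rng.random() < config.hub_cell_fraction
            lm = base_logmean.copy()
            stage = max(0, t_i - split + 1)
            if branch == "A":
                for g in drivers_a:
                    lm[gidx[g]] += config.drift * stage
            elif branch == "B":
                for g in drivers_b:
                    lm[gidx[g]] += config.drift * stage
            if hub_cell:
                for g in hubs:
                    lm[gidx[g]] += config.hub_boost
            if t_i == mid_stage:
                for g in rp:
                    lm[gidx[g]] += config.module_boost
            if t_i == split:
                for g in cc:
                    lm[gidx[g]] += config.module_boost
            rate = np.exp(lm)
            mu = config.library_size * rate / rate.sum()
            lam = rng.gamma(1.0 / config.dispersion, mu * config.dispersion)
            rows.append(rng.poisson(lam))
            obs_rows.append({
                "barcode": f"{tp}_c{c:04d}",
                "timepoint": tp,
                "day": tp,
                "branch": branch,
                "cluster": f"{branch}@{tp}",
                "high_degree_population": hub_cell,
            })

    X = np.vstack(rows).astype(np.int64)
    obs = pd.DataFrame(obs_rows).set_index("barcode")
    obs["timepoint"] = pd.Categorical(obs["timepoint"], categories=tps, ordered=True)
    adata = ad.AnnData(X=X, obs=obs)
    adata.var_names = genes

    # toy connectome: hubs connect to many flat genes, flat genes to few
    edges = []
    per_hub = max(10, n_flat // config.n_hub_genes)
    for h_i, h in enumerate(hubs):
        for k in range(per_hub):
            edges.append((h, flat[(h_i * per_hub + k) % n_flat]))
    # low-degree background links among flat genes
    for i in range(0, n_flat - 1, 2):
        edges.append((flat[i], flat[i + 1]))
    connectome_edges = pd.DataFrame(edges, columns=["a", "b"])

    # homology: mouse-cased gene -> uppercase "human" symbol, identity-shaped
    homology = pd.DataFrame({"source": genes, "human": [g.upper() for g in genes]})

    truth = TruthTable(
        cell_meta=obs,
        gene_sets={
            "drivers_A": drivers_a,
            "drivers_B": drivers_b,
            "hub_genes": hubs,
            "rp_genes": rp,
            "cell_cycle_genes": cc,
            "mito_genes": mito,
            "flat_genes": flat,
        },
    )
    return adata, truth, connectome_edges, homology


def simulate_hvg_matrix(
    n_cells: int = 300, n_flat: int = 2000, n_variable: int = 100, seed: int = 0
):
    """Toy matrix with planted high-variance genes among flat genes.

    Per-gene base means are spread over a range so planted genes compete
    inside mean bins dominated by flat genes.  Flat genes are Poisson around
    their base mean; variable genes get per-cell lognormal overdispersion at
    the same base mean.  Returns (AnnData, planted gene list).
    """
    import anndata as ad

    rng = np.random.default_rng(seed)
    base = rng.uniform(3.0, 30.0, size=n_flat + n_variable)
    flat = rng.poisson(base[:n_flat], size=(n_cells, n_flat))
    sigma = 0.9
    factor = np.exp(rng.normal(0.0, sigma, size=(n_cells, n_variable)) - sigma**2 / 2)
    var = rng.poisson(base[n_flat:] * factor)
    X = np.hstack([flat, var])
    names = [f"Flat{i:04d}" for i in range(n_flat)] + [
        f"Var{i:03d}" for i in range(n_variable)
    ]
    adata = ad.AnnData(X=X.astype(np.int64))
    adata.var_names = names
    adata.obs_names = [f"cell{i:04d}" for i in range(n_cells)]
    return adata, names[n_flat:]
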