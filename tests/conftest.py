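"""Shared seeded fixtures: simulated reads, alignments, and the two-branch
time course used across the entropy / similarity / transport tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fatemap.rna import normalize_ln_cpm100
from fatemap.simulate import (
    SimConfig,
    simulate_alignments,
    simulate_reads,
    simulate_timecourse,
    simulate_whitelists,
)


@pytest.fixture(scope="session")
def default_whitelist():
    return simulate_whitelists(SimConfig(seed=42))


@pytest.fixture(scope="session")
def clean_reads():
    """10k read pairs, zero sequencing errors."""
    cfg = SimConfig(seed=42, n_read_pairs=10_000, n_cells=100, error_rate=0.0)
    wl, truth, rec1, rec2 = simulate_reads(cfg)
    return cfg, wl, truth, rec1, rec2


@pytest.fixture(scope="session")
def aligned_fixture(tmp_path_factory):
    """Toy SAM with planted good/background cells and 10% duplicates."""
    out = tmp_path_factory.mktemp("sam") / "alignments.sam"
    cfg = SimConfig(seed=5, duplicate_rate=0.1)
    records, truth, tss = simulate_alignments(cfg, out_sam=out)
    return cfg, out, records, truth, tss


@pytest.fixture(scope="session")
def timecourse():
    """500 cells x 4 timepoints, branches A/B separating at the second
    timepoint, with planted drivers, hub (high-degree) population, and
    RP / cell-cycle pulses.  Normalized in place."""
    adata, truth, edges, homology = simulate_timecourse(SimConfig(seed=11))
    normalize_ln_cpm100(adata)
    return adata, truth, edges, homology


@pytest.fixture(scope="session")
def three_type_split(timecourse):
    """Two half-datasets over three well-separated simulated cell types."""
    adata, _, _, _ = timecourse
    obs = adata.obs
    mask = obs["cluster"].isin(["root@D0", "A@D35", "B@D35"]).to_numpy()
    counts = pd.DataFrame(
        np.asarray(adata.X)[mask], index=obs.index[mask], columns=adata.var_names
    )
    labels = obs.loc[mask, "cluster"].astype(str)
    rng = np.random.default_rng(0)
    idx = rng.permutation(len(counts))
    half = len(counts) // 2
    return (
        counts.iloc[idx[:half]],
        labels.iloc[idx[:half]],
        counts.iloc[idx[half:]],
        labels.iloc[idx[half:]],
    )
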