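"""Unbalanced entropic OT: solver limits, LP oracle, chain composition,
ancestor pull-back, divergence metric, trends, and driver ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linprog
from scipy.stats import spearmanr

from fatemap.transport import (
    AncestorDistribution,
    Coupling,
    OTParams,
    TransportChain,
    ancestor_divergence,
    compose_chain,
    driver_correlation,
    fit_chain,
    gene_trend,
    membership,
    ordered_timepoints,
    pull_back,
    squared_euclidean_cost,
    transport_map,
)


@pytest.fixture(scope="module")
def fitted_chain(request):
    adata, truth, _, _ = request.getfixturevalue("timecourse")
    return adata, fit_chain(adata, params=OTParams())


def lp_coupling(C, a, b):
    """Exact balanced-OT solution of a small instance by linear programming."""
    n, m = C.shape
    A_eq = []
    for i in range(n):
        row = np.zeros(n * m)
        row[i * m : (i + 1) * m] = 1
        A_eq.append(row)
    for j in range(m):
        row = np.zeros(n * m)
        row[j::m] = 1
        A_eq.append(row)
    res = linprog(
        C.ravel(), A_eq=np.array(A_eq), b_eq=np.concatenate([a, b]), bounds=(0, None)
    )
    assert res.success
    return res.x.reshape(n, m)


class TestOTParams:
    def test_defaults_are_the_timecourse_setting(self):
        p = OTParams()
        assert (p.lambda1, p.lambda2, p.epsilon, p.growth_iters) == (1.0, 50.0, 0.05, 1)

    @pytest.mark.parametrize("kw", [{"lambda1": 0}, {"epsilon": -1}, {"growth_iters": 0}])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            OTParams(**kw)


class TestTransportMap:
    def test_huge_epsilon_approaches_outer_product_of_marginals(self):
        rng = np.random.default_rng(3)
        X0, X1 = rng.normal(size=(6, 2)), rng.normal(size=(5, 2))
        c = transport_map(X0, X1, params=OTParams(epsilon=1e3))
        outer = np.full((6, 5), 1 / 30)
        assert np.abs(c.matrix.to_numpy() - outer).max() < 1e-3

    def test_identical_clouds_balanced_small_epsilon_concentrates_on_diagonal(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(5, 2)) * 5
        c = transport_map(X, X, params=OTParams(lambda1=1e4, lambda2=1e4, epsilon=0.01))
        assert np.trace(c.matrix.to_numpy()) >= 0.9

    def test_near_balanced_instance_matches_exact_lp_oracle(self):
        rng = np.random.default_rng(5)
        X0, X1 = rng.normal(size=(5, 2)) * 5, rng.normal(size=(5, 2)) * 5
        C = squared_euclidean_cost(X0, X1)
        a = b = np.full(5, 0.2)
        lp = lp_coupling(C, a, b)
        c = transport_map(
            X0, X1, params=OTParams(lambda1=1e5, lambda2=1e5, epsilon=0.002)
        )
        assert np.abs(lp - c.matrix.to_numpy()).max() < 1e-3

    def test_column_sums_near_uniform_at_default_lambda2(self, fitted_chain):
        _, chain = fitted_chain
        for coupling in chain.couplings.values():
            colsums = coupling.matrix.to_numpy().sum(axis=0)
            rel_err = np.abs(colsums * len(colsums) - 1.0)
            assert rel_err.max() < 0.01
            assert coupling.total_mass == pytest.approx(1.0)
            assert coupling.converged

    def test_growth_must_be_positive_and_dims_must_match(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError, match="growth"):
            transport_map(X, X, growth=np.array([1.0, 0.0, 1.0]))
        with pytest.raises(ValueError, match="dimensionality"):
            transport_map(X, np.zeros((3, 3)))

    def test_non_convergence_reported_not_raised(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(4, 2))
        c = transport_map(X, X, params=OTParams(max_sinkhorn_iters=2))
        assert not c.converged


def identity_chain(n=4, tps=("t0", "t1", "t2")):
    cells = {t: [f"{t}_c{i}" for i in range(n)] for t in tps}
    chain = TransportChain(timepoints=list(tps))
    for t0, t1 in zip(tps[:-1], tps[1:]):
        m = pd.DataFrame(np.eye(n) / n, index=cells[t0], columns=cells[t1])
        chain.add(t0, t1, Coupling(matrix=m, converged=True, n_iters=1))
    return chain, cells


class TestComposeAndPullBack:
    def test_adjacent_composition_returns_normalized_stored_coupling(self, fitted_chain):
        _, chain = fitted_chain
        t0, t1 = chain.timepoints[0], chain.timepoints[1]
        composed = compose_chain(chain, t0, t1)
        expected = chain.markov(t0, t1)
        expected = expected / expected.to_numpy().sum()
        pd.testing.assert_frame_equal(composed, expected)

    def test_identity_couplings_compose_to_identity(self):
        chain, cells = identity_chain()
        composed = compose_chain(chain, "t0", "t2")
        np.testing.assert_allclose(composed.to_numpy(), np.eye(4) / 4)

    def test_composed_pull_back_equals_sequential(self, fitted_chain):
        adata, chain = fitted_chain
        last = chain.timepoints[-1]
        targets = list(adata.obs.index[
            (adata.obs["timepoint"] == last) & (adata.obs["branch"] == "A")
        ])[:50]
        sequential = pull_back(targets, chain, last)
        p_target = pd.Series(0.0, index=chain.cell_ids[last])
        p_target[targets] = 1.0 / len(targets)
        for tp in chain.timepoints[:-1]:
            composed = compose_chain(chain, tp, last)
            direct = composed @ p_target
            direct = direct / direct.sum()
            assert np.abs(
                direct - sequential[tp].probabilities
            ).max() < 1e-10

    def test_identity_coupling_pull_back_of_everything_is_uniform(self):
        chain, cells = identity_chain()
        dists = pull_back(cells["t2"], chain, "t2")
        for tp in ("t0", "t1"):
            np.testing.assert_allclose(dists[tp].probabilities.to_numpy(), 0.25)

    def test_two_branch_ancestors_recovered(self, fitted_chain):
        """Ancestors of branch-A terminal cells sit on branch-A cells at the
        first post-split timepoint with >= 90% mass."""
        adata, chain = fitted_chain
        obs = adata.obs
        last = chain.timepoints[-1]
        split_tp = chain.timepoints[1]
        for branch in ("A", "B"):
            targets = list(obs.index[(obs["timepoint"] == last) & (obs["branch"] == branch)])
            dists = pull_back(targets, chain, last, target_name=branch)
            p = dists[split_tp].probabilities
            same_branch = obs.loc[p.index, "branch"] == branch
            assert p[same_branch.to_numpy()].sum() >= 0.9
            for tp, dist in dists.items():
                assert dist.probabilities.sum() == pytest.approx(1.0)

    def test_missing_target_cells_error(self, fitted_chain):
        _, chain = fitted_chain
        with pytest.raises(ValueError, match="absent"):
            pull_back(["nonexistent"], chain, chain.timepoints[-1])
        with pytest.raises(ValueError, match="empty"):
            pull_back([], chain, chain.timepoints[-1])


class TestMembership:
    def test_uniform_at_exact_threshold_is_empty(self):
        p = pd.Series(1 / 4000, index=[f"c{i}" for i in range(4000)])
        d = AncestorDistribution(timepoint="t", probabilities=p)
        assert membership(d, threshold=0.00025) == []

    def test_uniform_over_1000_all_selected(self):
        p = pd.Series(1 / 1000, index=[f"c{i}" for i in range(1000)])
        d = AncestorDistribution(timepoint="t", probabilities=p)
        assert len(membership(d)) == 1000

    def test_point_mass_is_singleton(self):
        p = pd.Series([1.0, 0.0, 0.0], index=["a", "b", "c"])
        d = AncestorDistribution(timepoint="t", probabilities=p)
        assert membership(d) == ["a"]


class TestAncestorDivergence:
    def s(self, vals, idx=None):
        return pd.Series(vals, index=idx or [f"c{i}" for i in range(len(vals))])

    def test_examples(self):
        assert ancestor_divergence(self.s([0.5, 0.5]), self.s([0.5, 0.5])) == 0.0
        assert ancestor_divergence(self.s([1.0, 0.0]), self.s([0.0, 1.0])) == 1.0
        assert ancestor_divergence(self.s([1.0, 0.0]), self.s([0.5, 0.5])) == 0.5

    def test_mismatched_index_error(self):
        with pytest.raises(ValueError, match="different cell indices"):
            ancestor_divergence(self.s([1.0], ["a"]), self.s([1.0], ["b"]))

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_metric_properties_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        p, q, r = (rng.dirichlet(np.ones(8)) for _ in range(3))
        idx = [f"c{i}" for i in range(8)]
        p, q, r = self.s(p, idx), self.s(q, idx), self.s(r, idx)
        d_pq = ancestor_divergence(p, q)
        assert 0.0 <= d_pq <= 1.0
        assert d_pq == pytest.approx(ancestor_divergence(q, p))
        assert ancestor_divergence(p, p) == 0.0
        assert d_pq <= ancestor_divergence(p, r) + ancestor_divergence(r, q) + 1e-12

    def test_branch_divergence_exceeds_within_fate_split(self, fitted_chain):
        """Ancestor divergence between the two terminal fates exceeds the
        divergence between two random halves of one fate."""
        adata, chain = fitted_chain
        obs = adata.obs
        last = chain.timepoints[-1]
        split_tp = chain.timepoints[1]
        targ = {
            b: list(obs.index[(obs["timepoint"] == last) & (obs["branch"] == b)])
            for b in ("A", "B")
        }
        d_ab = ancestor_divergence(
            pull_back(targ["A"], chain, last)[split_tp],
            pull_back(targ["B"], chain, last)[split_tp],
        )
        rng = np.random.default_rng(0)
        half = rng.permutation(targ["A"])
        d_within = ancestor_divergence(
            pull_back(list(half[: len(half) // 2]), chain, last)[split_tp],
            pull_back(list(half[len(half) // 2 :]), chain, last)[split_tp],
        )
        assert d_ab > d_within


class TestGeneTrendsAndDrivers:
    def test_point_mass_and_uniform_trends(self, timecourse):
        adata, *_ = timecourse
        obs = adata.obs
        t0 = "D0"
        cells = list(obs.index[obs["timepoint"] == t0])
        point = pd.Series(0.0, index=cells)
        point.iloc[0] = 1.0
        uniform = pd.Series(1.0 / len(cells), index=cells)
        trend = gene_trend(adata, {t0: point}, genes=["DrvA000", "Gene0000"])
        row = np.asarray(adata[cells[0]].layers["normalized"]).ravel()
        names = list(adata.var_names)
        assert trend.loc[t0, "DrvA000"] == pytest.approx(row[names.index("DrvA000")])
        trend_u = gene_trend(adata, {t0: uniform}, genes=["Gene0000"])
        mean = np.asarray(adata[cells].layers["normalized"]).mean(axis=0)
        assert trend_u.loc[t0, "Gene0000"] == pytest.approx(mean[names.index("Gene0000")])

    def test_planted_driver_trend_rises_along_ancestor_path(self, fitted_chain, timecourse):
        adata, chain = fitted_chain
        _, truth, _, _ = timecourse
        obs = adata.obs
        last = chain.timepoints[-1]
        targets = list(obs.index[(obs["timepoint"] == last) & (obs["branch"] == "A")])
        dists = pull_back(targets, chain, last)
        dists[last] = pd.Series(
            np.where(pd.Index(chain.cell_ids[last]).isin(targets), 1 / len(targets), 0.0),
            index=chain.cell_ids[last],
        )
        trend = gene_trend(adata, dists, genes=truth.gene_sets["drivers_A"])
        order = [chain.timepoints.index(t) for t in trend.index]
        for gene in trend.columns[:10]:
            rho = spearmanr(order, trend[gene].to_numpy()).statistic
            assert rho > 0.9

    def test_driver_correlation_examples_and_planted_recovery(self, timecourse):
        adata, truth, _, _ = timecourse
        rng = np.random.default_rng(1)
        # fate probability: high for branch A cells
        fate = pd.Series(
            np.where(adata.obs["branch"] == "A", 0.9, 0.1), index=adata.obs_names
        )
        ranked = driver_correlation(adata, fate)
        top_decile = set(ranked.index[: len(ranked) // 10])
        assert set(truth.gene_sets["drivers_A"]) <= top_decile
        # a gene equal to the fate vector ranks first with correlation 1
        import anndata as ad

        toy = ad.AnnData(
            X=np.column_stack([fate.to_numpy(), rng.random(len(fate)), np.ones(len(fate))])
        )
        toy.obs_names = list(adata.obs_names)
        toy.var_names = ["fate_gene", "noise", "constant"]
        r = driver_correlation(toy, fate)
        assert r.index[0] == "fate_gene"
        assert r["fate_gene"] == pytest.approx(1.0)
        assert np.isnan(r["constant"]) and r.index[-1] == "constant"

    def test_permuted_fate_gives_small_correlations(self, timecourse):
        adata, *_ = timecourse
        rng = np.random.default_rng(2)
        fate = pd.Series(rng.permutation(rng.random(adata.n_obs)), index=adata.obs_names)
        r = driver_correlation(adata, fate)
        assert np.nanmean(np.abs(r.to_numpy())) < 0.1

    def test_constant_fate_vector_errors(self, timecourse):
        adata, *_ = timecourse
        fate = pd.Series(0.5, index=adata.obs_names)
        with pytest.raises(ValueError, match="constant"):
            driver_correlation(adata, fate)


def test_ordered_timepoints_handles_day_labels_and_numbers():
    assert ordered_timepoints(pd.Series(["D12", "D0", "D35", "D6"])) == [
        "D0", "D6", "D12", "D35",
    ]
    assert ordered_timepoints(pd.Series([3, 1, 2])) == [1, 2, 3]
    cat = pd.Series(pd.Categorical(["b", "a"], categories=["b", "a"], ordered=True))
    assert ordered_timepoints(cat) == ["b", "a"]
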