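"""Association networks: partial Spearman, bootstrap, variability, export."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import networkx as nx
import nptnet
from nptnet.errors import DegenerateVariableError, InputError, PairingError
from nptnet.networks import (
    bootstrap_networks,
    build_association_network,
    edge_confidence_intervals,
    export_network,
    partial_spearman,
    variability_network,
)
from nptnet.synthetic import (
    CohortConfig,
    emulate_parameter_table,
    null_config,
    planted_change_table,
    planted_prediction_table,
)
from nptnet.tables import session_column


def rank_regression_oracle(x, y, covariates):
    """Brute-force partial Spearman: explicit normal equations on ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rc = np.column_stack([np.ones(len(x))] + [
        stats.rankdata(c) for c in np.atleast_2d(covariates.T)
    ])
    bx = np.linalg.solve(rc.T @ rc, rc.T @ rx)
    by = np.linalg.solve(rc.T @ rc, rc.T @ ry)
    ex, ey = rx - rc @ bx, ry - rc @ by
    return float(np.corrcoef(ex, ey)[0, 1])


class TestPartialSpearman:
    def test_perfect_monotone(self):
        x = np.arange(20.0)
        y = np.exp(x / 5.0)
        rho, p = partial_spearman(x, y)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_matches_rank_regression_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 60))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            cov = np.column_stack(
                [rng.standard_normal(n), (rng.random(n) < 0.5).astype(float)]
            )
            rho, _ = partial_spearman(x, y, cov)
            assert rho == pytest.approx(rank_regression_oracle(x, y, cov), abs=1e-10)

    def test_hand_table_with_one_covariate(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0, 2.0, 6.0, 5.5, 3.5])
        y = np.array([2.0, 0.5, 3.0, 2.5, 4.0, 8.0, 1.0, 7.0, 6.0, 2.2])
        z = np.array([1.0, 2.0, 1.5, 0.5, 3.0, 2.5, 1.1, 2.8, 0.9, 1.3])
        rho, _ = partial_spearman(x, y, z[:, None])
        assert rho == pytest.approx(rank_regression_oracle(x, y, z[:, None]), abs=1e-12)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        n = 35
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        y = 0.6 * x + 0.4 * z + rng.standard_normal(n)
        g = (rng.random(n) < 0.5).astype(float)
        df = pd.DataFrame({"x": x, "y": y, "z": z, "g": g})
        res = pg.partial_corr(df, "x", "y", covar=["z", "g"], method="spearman")
        rho, p = partial_spearman(x, y, np.column_stack([z, g]))
        assert rho == pytest.approx(res["r"].iloc[0], abs=1e-10)
        assert p == pytest.approx(res["p_val"].iloc[0], abs=1e-10)

    def test_reduces_to_plain_spearman_without_covariates(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 50))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            rho, p = partial_spearman(x, y)
            sp = stats.spearmanr(x, y)
            assert rho == pytest.approx(sp.statistic, abs=1e-12)
            assert p == pytest.approx(sp.pvalue, abs=1e-9)

    def test_confounder_removed(self):
        """x and y driven only by a shared covariate: adjusted rho is null."""
        significant = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            z = r.standard_normal(200)
            x = z + r.standard_normal(200)
            y = z + r.standard_normal(200)
            _, p = partial_spearman(x, y, z[:, None])
            significant += p < 0.05
        assert significant <= 10

    def test_constant_variable_rejected(self):
        with pytest.raises(DegenerateVariableError):
            partial_spearman(np.ones(10), np.arange(10.0))

    def test_permutation_method_agrees_with_t(self, rng):
        n = 8  # full enumeration regime
        x = rng.standard_normal(n)
        y = x + 0.3 * rng.standard_normal(n)
        _, p_t = partial_spearman(x, y)
        _, p_perm = partial_spearman(x, y, method="permutation")
        assert p_perm == pytest.approx(p_t, abs=0.08)


class TestNetworkBuild:
    def test_duplicate_column_gives_unit_edge(self):
        table = emulate_parameter_table(CohortConfig(seed=3))
        df = table.df.copy()
        df[session_column("SEF", "pre")] = df[session_column("MF", "pre")]
        net = build_association_network(nptnet.ParameterTable(df), "pre")
        edge = next(
            e for e in net.edges if {e.u, e.v} == {"MF", "SEF"}
        )
        assert edge.weight == pytest.approx(1.0)
        assert edge.p_value == 0.0

    def test_all_weights_and_pvalues_valid(self):
        net = build_association_network(
            emulate_parameter_table(CohortConfig(seed=5)), "pre"
        )
        assert len(net.nodes) == 28
        for e in net.edges:
            assert 0 < e.weight <= 1
            assert e.weight == abs(e.rho_signed)
            assert e.p_value < net.alpha

    def test_mode_node_naming(self):
        table = emulate_parameter_table(CohortConfig(seed=5))
        assert all(
            n.endswith(" Var")
            for n in build_association_network(table, "changes").nodes
        )
        pred = build_association_network(table, "prediction").nodes
        assert "MMSE Var" in pred and "DBD-13 Var" in pred
        assert "MMSE" not in pred
        assert len(pred) == 28

    def test_unknown_mode(self):
        table = emulate_parameter_table(CohortConfig(seed=5))
        with pytest.raises(InputError):
            build_association_network(table, "sideways")

    def test_edges_invariant_to_monotone_transforms(self):
        table = emulate_parameter_table(CohortConfig(seed=11))
        net_a = build_association_network(table, "pre")
        df = table.df.copy()
        df[session_column("SEF", "pre")] = np.exp(
            df[session_column("SEF", "pre")] / 30.0
        )
        df[session_column("LZC", "pre")] = np.log(df[session_column("LZC", "pre")] + 1)
        net_b = build_association_network(nptnet.ParameterTable(df), "pre")
        edges_a = {(e.u, e.v): e.weight for e in net_a.edges}
        edges_b = {(e.u, e.v): e.weight for e in net_b.edges}
        assert edges_a.keys() == edges_b.keys()
        for k in edges_a:
            assert edges_a[k] == pytest.approx(edges_b[k], abs=1e-10)

    def test_planted_prediction_edge_recovered(self):
        table = planted_prediction_table(100, 0.8, seed=6)
        net = build_association_network(table, "prediction")
        edge = next(
            e for e in net.edges if {e.u, e.v} == {"RP(Beta1)", "MMSE Var"}
        )
        assert edge.weight == pytest.approx(0.8, abs=0.1)
        assert edge.rho_signed > 0


@pytest.fixture(scope="module")
def table():
    return emulate_parameter_table(CohortConfig(seed=8))


@pytest.fixture(scope="module")
def net():
    return build_association_network(
        emulate_parameter_table(CohortConfig(seed=14)), "pre"
    )


class TestBootstrap:
    def test_fixed_seed_reproducible(self, table):
        a = bootstrap_networks(table, "pre", n_iterations=50, seed=4)
        b = bootstrap_networks(table, "pre", n_iterations=50, seed=4)
        assert np.array_equal(a.resample_matrix, b.resample_matrix)
        assert np.array_equal(a.weights, b.weights, equal_nan=True)

    def test_identity_resample_equals_point_estimates(self, table):
        n = table.n_subjects
        identity = np.arange(n)[None, :]
        ens = bootstrap_networks(table, "pre", n_iterations=1, resample_matrix=identity)
        full = build_association_network(table, "pre", alpha=1.01)
        point = {(e.u, e.v): e.weight for e in full.edges}
        for (u, v), w in zip(ens.edge_index, ens.weights[0]):
            assert w == pytest.approx(point[(u, v)], abs=1e-10)

    def test_ci_contains_point_estimate_and_shrinks(self):
        widths = {}
        for n in (19, 100):
            table = planted_change_table(n, 0.8, 0.8, seed=9)
            ens = bootstrap_networks(table, "pre", n_iterations=400, seed=2)
            ci = edge_confidence_intervals(ens)
            row = ci[
                ((ci.node1 == "RP(Beta1)") & (ci.node2 == "MF"))
                | ((ci.node1 == "MF") & (ci.node2 == "RP(Beta1)"))
            ].iloc[0]
            x = table.session_values("pre")["RP(Beta1)"]
            y = table.session_values("pre")["MF"]
            rho, _ = partial_spearman(x, y, table.covariates().to_numpy())
            assert row.ci_low - 0.05 <= abs(rho) <= row.ci_high + 0.05
            widths[n] = row.ci_high - row.ci_low
        assert widths[100] < widths[19]


class TestVariability:
    def test_cloned_ensembles_degenerate(self):
        table = emulate_parameter_table(CohortConfig(seed=10))
        ens = bootstrap_networks(table, "pre", n_iterations=40, seed=3)
        net = variability_network(ens, ens)
        assert all(e.weight == 0.0 for e in net.edges)
        assert "degenerate-top-set" in net.flags
        assert len(net.edges) == int(np.ceil(0.05 * 378))

    def test_planted_change_detected(self):
        table = planted_change_table(50, 0.0, 0.8, seed=12)
        pre = bootstrap_networks(table, "pre", n_iterations=300, seed=5)
        post = bootstrap_networks(table, "post", n_iterations=300, seed=5)
        net = variability_network(pre, post)
        assert any({e.u, e.v} == {"RP(Beta1)", "MF"} for e in net.edges)

    def test_top_fraction_one_keeps_everything(self):
        table = emulate_parameter_table(CohortConfig(seed=10))
        pre = bootstrap_networks(table, "pre", n_iterations=30, seed=3)
        post = bootstrap_networks(table, "post", n_iterations=30, seed=3)
        net = variability_network(pre, post, top_fraction=1.0)
        assert len(net.edges) == 378

    def test_mismatched_resamples_rejected(self):
        table = emulate_parameter_table(CohortConfig(seed=10))
        a = bootstrap_networks(table, "pre", n_iterations=30, seed=3)
        b = bootstrap_networks(table, "post", n_iterations=30, seed=4)
        with pytest.raises(PairingError):
            variability_network(a, b)

    def test_statistic_agrees_with_own_wilcoxon(self):
        """The |z| edge weight matches the outcome module's approximation."""
        from nptnet.networks import _paired_wilcoxon_z
        from nptnet.outcomes import wilcoxon_signed_rank

        rng = np.random.default_rng(0)
        pre = rng.random(200)
        post = pre + 0.05 * rng.standard_normal(200) + 0.02
        z, p = _paired_wilcoxon_z(pre, post)
        ours = wilcoxon_signed_rank(pre, post, "two-sided", method="approx")
        # continuity correction differs; the standardized statistics align
        assert abs(z) == pytest.approx(
            abs(stats.norm.isf(ours.p_value / 2)), rel=0.02
        )


class TestNullCalibrationSmall:
    def test_null_retention_close_to_alpha(self):
        rates = [
            len(build_association_network(
                emulate_parameter_table(null_config(n_subjects=60, seed=500 + s)),
                "pre",
            ).edges) / 378
            for s in range(40)
        ]
        assert np.mean(rates) == pytest.approx(0.05, abs=0.02)


class TestExport:
    def test_gexf_round_trip(self, net, tmp_path):
        path = export_network(net, tmp_path / "net.gexf", "gexf")
        g = nx.read_gexf(path)
        ours = net.to_graph()
        assert nx.is_isomorphic(g, ours)
        assert set(g.nodes) == set(ours.nodes)
        for u, v, data in ours.edges(data=True):
            assert g[u][v]["weight"] == pytest.approx(data["weight"])

    def test_edge_csv_ordering_matches_gexf(self, net, tmp_path):
        gexf = nx.read_gexf(export_network(net, tmp_path / "n.gexf", "gexf"))
        edges = pd.read_csv(export_network(net, tmp_path / "e.csv", "edge-csv"))
        assert (edges.weight.values[:-1] >= edges.weight.values[1:]).all()
        for row in edges.itertuples():
            assert gexf[row.node1][row.node2]["weight"] == pytest.approx(row.weight)

    def test_empty_network_still_valid(self, tmp_path):
        from nptnet.networks import AssociationNetwork

        empty = AssociationNetwork(
            mode="pre", nodes=list(nptnet.ANALYSIS_VARIABLES), edges=[]
        )
        g = nx.read_gexf(export_network(empty, tmp_path / "empty.gexf", "gexf"))
        assert g.number_of_nodes() == 28 and g.number_of_edges() == 0
        nodes = pd.read_csv(export_network(empty, tmp_path / "n.csv", "node-csv"))
        assert (nodes.degree == 0).all()

    def test_unknown_format(self, net, tmp_path):
        with pytest.raises(InputError):
            export_network(net, tmp_path / "x", "graphml")
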