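import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import grndyn as g
from grndyn.hill import FitConfig, HillParameters, KnockdownSpec, hill_nonlinearity
from grndyn.network import GeneNetwork, read_edge_list
from grndyn.prep import BinnedTimeSeries


def _params(genes, W, u, tau, x0=None):
    return HillParameters(
        gene_names=genes,
        W_in=np.asarray(W, dtype=float),
        u=np.asarray(u, dtype=float),
        tau=tau,
        x0_per_branch=x0 or {},
    )


@pytest.fixture
def single_gene_basal():
    """One gene, no edges, u = 1: H = 0.5 everywhere, relaxation to 0.5."""
    return _params(("g1",), [[0.0]], [1.0], 1.0)


class TestHillRHS:
    def test_origin_is_fixed_point_without_drive(self):
        p = _params(("a", "b"), np.zeros((2, 2)), [0.0, 0.0], 1.0)
        assert np.allclose(g.hill_rhs(np.zeros(2), p), 0.0)

    def test_single_activator_hand_value(self):
        # W(a->b) = 2, x_a = 0.5, x_b = 0.1: H_b = 0.25/1.25 = 0.2, dx_b = 0.1
        p = _params(("a", "b"), [[0.0, 2.0], [0.0, 0.0]], [0.0, 0.0], 1.0)
        dx = g.hill_rhs(np.array([0.5, 0.1]), p)
        assert dx[1] == pytest.approx(0.1)

    def test_saturated_repressor_zeroes_numerator(self):
        p = _params(("a", "b"), [[0.0, -1.0], [0.0, 0.0]], [0.0, 0.0], 2.0)
        dx = g.hill_rhs(np.array([1.0, 0.3]), p)
        assert dx[1] == pytest.approx(-0.3 / 2.0)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            _params(("a",), [[0.0]], [0.0], 0.0)

    def test_non_finite_state_rejected(self, single_gene_basal):
        with pytest.raises(ValueError, match="finite"):
            g.hill_rhs(np.array([np.nan]), single_gene_basal)

    @given(st.integers(0, 10_000))
    def test_nonlinearity_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 6))
        W = rng.uniform(-5, 5, (m, m))
        u = rng.uniform(0, 5, m)
        x = rng.uniform(0, 3, m)
        H = hill_nonlinearity(x, W, u)
        assert np.all(H >= 0) and np.all(H < 1)


class TestSimulate:
    def test_fixed_point_stays_constant(self):
        p = _params(("a",), [[0.0]], [0.0], 1.0)
        traj = g.simulate(p, np.zeros(1), np.linspace(0, 5, 11))
        assert np.allclose(traj, 0.0)

    def test_closed_form_relaxation(self, single_gene_basal):
        t = np.linspace(0, 4, 41)
        traj = g.simulate(single_gene_basal, np.zeros(1), t)
        expected = 0.5 * (1 - np.exp(-t))
        assert traj[0] == pytest.approx(expected, rel=1e-5, abs=1e-8)

    def test_forward_invariance_random_parameters(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            m = int(rng.integers(1, 5))
            p = _params(
                tuple(f"g{i}" for i in range(m)),
                rng.uniform(-5, 5, (m, m)),
                rng.uniform(0, 5, m),
                float(rng.uniform(0.05, 5)),
            )
            traj = g.simulate(p, rng.uniform(0, 1, m), np.linspace(0, 2, 21))
            assert np.all(traj >= 0) and np.all(traj <= 1)

    def test_x0_outside_unit_box_rejected(self, single_gene_basal):
        with pytest.raises(ValueError, match="x0"):
            g.simulate(single_gene_basal, np.array([1.5]), [0, 1])


class TestKnockdown:
    def test_zero_strength_is_identity(self, single_gene_basal):
        t = np.linspace(0, 3, 16)
        base = g.simulate(single_gene_basal, np.zeros(1), t)
        kd = g.knockdown_simulate(
            single_gene_basal, KnockdownSpec("g1", k=0.0), np.zeros(1), t
        )
        assert np.allclose(base, kd, atol=1e-7)

    def test_k2_equilibrium_is_one_sixth(self, single_gene_basal):
        # dx = -(k+1)x + 0.5 with k = 2 -> equilibrium 0.5/3
        t = np.linspace(0, 40, 81)
        kd = g.knockdown_simulate(
            single_gene_basal, KnockdownSpec("g1", k=2.0), np.zeros(1), t
        )
        assert kd[0, -1] == pytest.approx(1 / 6, rel=1e-5)

    def test_unknown_gene_rejected(self, single_gene_basal):
        with pytest.raises(KeyError):
            g.knockdown_simulate(
                single_gene_basal, KnockdownSpec("gX"), np.zeros(1), [0, 1]
            )

    def test_negative_strength_rejected(self):
        with pytest.raises(ValueError):
            KnockdownSpec("g1", k=-1.0)


class TestTotalLoss:
    def _perfect_instance(self):
        p = _params(
            ("a", "b"),
            [[1.0, 2.0], [0.0, 0.5]],
            [0.3, 0.0],
            0.5,
            x0={"b0": np.array([0.2, 0.1])},
        )
        t = np.linspace(0.0, 1.0, 21)
        from grndyn.hill import _batch_trajectory

        traj = _batch_trajectory(
            p.x0_per_branch["b0"][None], p.W_in[None], p.u[None],
            np.array([p.tau]), t, 0.02,
        )[0].T
        series = BinnedTimeSeries("b0", t, traj, np.ones(len(t), int), ("a", "b"))
        return p, [series]

    def test_perfect_fit_leaves_only_regularizer(self):
        p, series = self._perfect_instance()
        cfg = FitConfig()
        total, comp = g.total_loss(p, series, cfg)
        assert comp["L_model"] == pytest.approx(0.0, abs=1e-12)
        assert comp["L_IC"] == pytest.approx(0.0, abs=1e-12)
        assert total == pytest.approx(cfg.lambda_p * comp["L_p"])

    def test_l1_counts_weights_u_and_tau(self):
        p, series = self._perfect_instance()
        _, comp = g.total_loss(p, series, FitConfig())
        assert comp["L_p"] == pytest.approx(1.0 + 2.0 + 0.5 + 0.3 + 0.5)

    def test_ic_weight_scales_linearly(self):
        p, series = self._perfect_instance()
        shifted = _params(
            p.gene_names, p.W_in, p.u, p.tau, x0={"b0": np.array([0.4, 0.1])}
        )
        _, c1 = g.total_loss(shifted, series, FitConfig(lambda_ic=10))
        _, c2 = g.total_loss(shifted, series, FitConfig(lambda_ic=20))
        assert c1["L_IC"] == c2["L_IC"] > 0
        assert c2["L_total"] - c2["L_model"] - 0.001 * c2["L_p"] == pytest.approx(
            2 * (c1["L_total"] - c1["L_model"] - 0.001 * c1["L_p"])
        )

    def test_missing_branch_rejected(self):
        p, series = self._perfect_instance()
        bad = _params(p.gene_names, p.W_in, p.u, p.tau, x0={"other": np.zeros(2)})
        with pytest.raises(ValueError, match="branch"):
            g.total_loss(bad, series, FitConfig())


class TestFit:
    def test_empty_series_rejected(self):
        net = read_edge_list("a,b")
        with pytest.raises(ValueError):
            g.fit(net, [], FitConfig())

    def test_default_loss_weights(self):
        cfg = FitConfig()
        assert cfg.lambda_p == 0.001 and cfg.lambda_ic == 10.0

    def test_self_consistency_recovery_and_edge_mask(self):
        """Model-generated data on a 2-gene chain is re-fitted to low error."""
        net = GeneNetwork(
            ("g1", "g2"),
            frozenset({("g1", "g1"), ("g1", "g2")}),
            {("g1", "g1"): 1, ("g1", "g2"): 1},
        )
        true = _params(
            ("g1", "g2"), [[2.0, 1.5], [0.0, 0.0]], [0.4, 0.0], 0.3,
            x0={"b0": np.array([0.15, 0.1])},
        )
        t = np.linspace(0.05, 0.95, 19)
        traj = g.simulate(true, true.x0_per_branch["b0"], t)
        series = [BinnedTimeSeries("b0", t, traj, np.ones(len(t), int), ("g1", "g2"))]
        res = g.fit(net, series, FitConfig(seed=2, max_generations=200))
        mse = res.loss_components["L_model"] / traj.size
        assert mse < 1e-2
        assert res.params.compatible_with(net)
        # loss identity within reported components
        c = res.loss_components
        assert c["L_total"] == pytest.approx(
            c["L_model"] + 0.001 * c["L_p"] + 10.0 * c["L_IC"], abs=1e-9
        )

    def test_same_seed_reproducible(self):
        net = read_edge_list("a,b,+")
        t = np.linspace(0.0, 1.0, 6)
        vals = np.array([[0.2, 0.3, 0.4, 0.5, 0.55, 0.6],
                         [0.1, 0.2, 0.35, 0.5, 0.6, 0.65]])
        series = [BinnedTimeSeries("b0", t, vals, np.ones(6, int), ("a", "b"))]
        cfg = FitConfig(seed=3, max_generations=15)
        r1 = g.fit(net, series, cfg)
        r2 = g.fit(net, series, cfg)
        assert r1.loss_components == r2.loss_components
        assert np.array_equal(r1.params.W_in, r2.params.W_in)

    def test_stronger_l1_does_not_increase_parameter_norm(self):
        net = read_edge_list("a,b,+")
        t = np.linspace(0.0, 1.0, 8)
        vals = np.vstack([np.linspace(0.2, 0.6, 8), np.linspace(0.1, 0.7, 8)])
        series = [BinnedTimeSeries("b0", t, vals, np.ones(8, int), ("a", "b"))]
        lp = []
        for lam in (0.001, 1.0):
            res = g.fit(net, series, FitConfig(seed=4, max_generations=120, lambda_p=lam))
            lp.append(res.loss_components["L_p"])
        assert lp[1] <= lp[0] + 1e-9


class TestClassifyFit:
    def _toggle_params(self, w34, w35, u=None, x0_g4=None, x0_g5=None):
        genes = ("g3", "g4", "g5")
        W = np.zeros((3, 3))
        # cubic-Hill toggle needs self-activation above 27/4 to be bistable
        W[1, 1], W[2, 2] = 10.0, 10.0
        W[1, 2], W[2, 1] = -10.0, -10.0
        W[0, 1], W[0, 2] = w34, w35
        return _params(
            genes, W, u if u is not None else [1.0, 0.0, 0.0], 0.2,
            x0={
                "g4": x0_g4 if x0_g4 is not None else np.array([0.3, 0.7, 0.1]),
                "g5": x0_g5 if x0_g5 is not None else np.array([0.3, 0.1, 0.7]),
            },
        )

    def _net(self):
        return read_edge_list(
            "g3,g4,+\ng3,g5,+\ng4,g4,+\ng5,g5,+\ng4,g5,-\ng5,g4,-"
        )

    def _classify(self, params):
        res = g.FitResult(params=params, loss_components={}, generations_run=0)
        return g.classify_fit(res, self._net(), ("g3", ("g4", "g5")))

    def test_collapsed_branches_labelled_no_bistability(self):
        same = np.array([0.3, 0.4, 0.4])
        p = self._toggle_params(0.0, 0.0, u=[0.0, 0.0, 0.0], x0_g4=same, x0_g5=same)
        assert self._classify(p) == "no_bistability"

    def test_reporter_dominant_drive_is_mechanism_recovered(self):
        p = self._toggle_params(w34=0.1, w35=2.0)
        assert self._classify(p) == "mechanism_recovered"

    def test_other_arm_dominant_drive_is_damaged_like(self):
        p = self._toggle_params(w34=2.0, w35=0.0)
        assert self._classify(p) == "damaged_like"

    def test_unconnected_arms_are_decoupled(self):
        p = self._toggle_params(w34=0.05, w35=0.05)
        assert self._classify(p) == "decoupled"

    def test_single_branch_rejected(self):
        p = self._toggle_params(1.0, 1.0)
        p = _params(p.gene_names, p.W_in, p.u, p.tau,
                    x0={"g4": p.x0_per_branch["g4"]})
        res = g.FitResult(params=p, loss_components={}, generations_run=0)
        with pytest.raises(ValueError, match="two branch"):
            g.classify_fit(res, self._net(), ("g3", ("g4", "g5")))

    def test_unknown_focus_gene_rejected(self):
        p = self._toggle_params(1.0, 1.0)
        res = g.FitResult(params=p, loss_components={}, generations_run=0)
        with pytest.raises(KeyError):
            g.classify_fit(res, self._net(), ("gX", ("g4", "g5")))


def test_fit_result_json_round_trip():
    p = _params(("a", "b"), [[0.0, 1.0], [0.0, 0.0]], [0.1, 0.0], 0.7,
                x0={"b0": np.array([0.2, 0.3])})
    res = g.FitResult(
        params=p,
        loss_components={"L_model": 1.0, "L_p": 2.0, "L_IC": 0.0, "L_total": 1.002},
        generations_run=10,
        classification="damaged_like",
    )
    again = g.FitResult.from_json(res.to_json())
    assert again.classification == "damaged_like"
    assert np.allclose(again.params.W_in, p.W_in)
    assert again.params.x0_per_branch["b0"] == pytest.approx([0.2, 0.3])
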