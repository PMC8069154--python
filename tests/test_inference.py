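"""The two belief-update schemes, trajectory recording and simulated LFPs."""

import numpy as np
import pytest

from actinf.free_energy import exact_posterior, free_energy, free_energy_gradient
from actinf.geometry import floor_beliefs, geodesic_distance, softmax
from actinf.inference import ai_update, ng_update, run_inference, simulated_lfp

from conftest import random_belief, random_context


def tv(a, b):
    return 0.5 * float(np.abs(np.asarray(a) - np.asarray(b)).sum())


class TestUpdateRules:
    @pytest.mark.parametrize("update", [ai_update, ng_update])
    def test_exact_posterior_is_fixed_point(self, rng, update):
        for _ in range(20):
            ctx = random_context(rng, 4)
            post = exact_posterior(ctx)
            np.testing.assert_allclose(update(post, ctx, 0.25), post, atol=1e-12)

    @pytest.mark.parametrize("update", [ai_update, ng_update])
    def test_zero_step_is_identity(self, rng, update):
        ctx = random_context(rng, 4)
        s = floor_beliefs(random_belief(rng, 4))
        np.testing.assert_allclose(update(s, ctx, 0.0), s, atol=1e-12)

    def test_ai_update_is_multiplicative_form(self, rng):
        # softmax(ln s - eps g) == (s * exp(-eps g)) / sum(...)
        for _ in range(20):
            ctx = random_context(rng, 4)
            s = floor_beliefs(random_belief(rng, 4))
            g = free_energy_gradient(s, ctx)
            mult = s * np.exp(-0.25 * g)
            np.testing.assert_allclose(ai_update(s, ctx, 0.25), mult / mult.sum(), atol=1e-12)

    def test_ng_update_is_projected_natural_step(self, rng):
        for _ in range(20):
            ctx = random_context(rng, 4)
            s = floor_beliefs(random_belief(rng, 4))
            g = free_energy_gradient(s, ctx)
            raw = s - 0.05 * s * g
            if raw.min() > 0:
                np.testing.assert_allclose(
                    ng_update(s, ctx, 0.05), raw / raw.sum(), atol=1e-12
                )

    def test_schemes_agree_to_second_order(self, rng):
        """Richardson check: halving eps shrinks the scheme discrepancy ~4x."""
        ratios = []
        for _ in range(200):
            ctx = random_context(rng, 4, scale=1.0)
            s = random_belief(rng, 4)
            d1 = np.linalg.norm(ai_update(s, ctx, 0.1) - ng_update(s, ctx, 0.1))
            d2 = np.linalg.norm(ai_update(s, ctx, 0.05) - ng_update(s, ctx, 0.05))
            if d2 > 1e-13:
                ratios.append(d1 / d2)
        assert 3.0 <= np.median(ratios) <= 5.0
        assert np.mean([(3.0 <= r <= 5.0) for r in ratios]) > 0.8


class TestRunInference:
    @pytest.mark.parametrize("scheme", ["active_inference", "natural_gradient"])
    def test_converges_to_oracle(self, rng, scheme):
        for _ in range(30):
            ctx = random_context(rng, 3)
            trace = run_inference(random_belief(rng, 3), ctx, scheme=scheme, eps=0.25)
            assert tv(trace.beliefs[-1], exact_posterior(ctx)) < 1e-3

    @pytest.mark.parametrize("scheme", ["active_inference", "natural_gradient"])
    def test_iterates_stay_on_simplex(self, rng, scheme):
        ctx = random_context(rng, 5, scale=3.0)
        trace = run_inference(random_belief(rng, 5), ctx, scheme=scheme)
        assert np.all(trace.beliefs >= 0)
        np.testing.assert_allclose(trace.beliefs.sum(axis=1), 1.0, atol=1e-10)

    def test_beliefs_are_softmax_of_voltages(self, rng):
        ctx = random_context(rng, 4)
        trace = run_inference(random_belief(rng, 4), ctx)
        for s, v in zip(trace.beliefs, trace.voltages):
            np.testing.assert_allclose(s, softmax(v), atol=1e-10)

    @pytest.mark.parametrize("scheme", ["active_inference", "natural_gradient"])
    @pytest.mark.parametrize("eps", [0.05, 0.25])
    def test_free_energy_monotone(self, rng, scheme, eps):
        for _ in range(20):
            ctx = random_context(rng, 4)
            trace = run_inference(random_belief(rng, 4), ctx, scheme=scheme, eps=eps)
            assert np.all(np.diff(trace.free_energies) <= 1e-8)

    def test_terminal_free_energy_identity(self, rng):
        """F(final) = -ln P(o) + KL(final || posterior)."""
        for _ in range(10):
            ctx = random_context(rng, 4)
            trace = run_inference(random_belief(rng, 4), ctx)
            post = floor_beliefs(exact_posterior(ctx))
            log_evidence = -free_energy(exact_posterior(ctx), ctx)
            s = floor_beliefs(trace.beliefs[-1])
            kl = float(np.sum(s * (np.log(s) - np.log(post))))
            assert trace.free_energies[-1] == pytest.approx(-log_evidence + kl, abs=1e-6)

    def test_path_length_bounded_below_by_geodesic(self, rng):
        from actinf.geometry import information_distance

        for scheme in ("active_inference", "natural_gradient"):
            for _ in range(20):
                ctx = random_context(rng, 4, scale=2.0)
                s0 = random_belief(rng, 4)
                # arc accumulation dominates the endpoint geodesic exactly
                trace = run_inference(s0, ctx, scheme=scheme, distance="arc")
                geo = geodesic_distance(trace.beliefs[0], trace.beliefs[-1])
                assert trace.info_path.total_length >= geo - 1e-9
                # chord accumulation dominates the endpoint chord
                trace_c = run_inference(s0, ctx, scheme=scheme, distance="chord")
                chord = information_distance(trace_c.beliefs[0], trace_c.beliefs[-1])
                assert trace_c.info_path.total_length >= chord - 1e-9

    def test_nonconvergence_flag_no_exception(self, rng):
        ctx = random_context(rng, 4, scale=4.0)
        trace = run_inference(random_belief(rng, 4), ctx, max_iter=2, tol=1e-12)
        assert not trace.converged
        assert trace.iterations == 2

    def test_discrepancy_shrinks_with_step_size(self, rng):
        """Scheme equivalence degrades gracefully: max path-length gap falls with eps."""
        problems = [(random_context(rng, 4, scale=1.5), random_belief(rng, 4)) for _ in range(20)]
        gaps = []
        for eps in (0.5, 0.25, 0.1):
            gap = 0.0
            for ctx, s0 in problems:
                ta = run_inference(s0, ctx, "active_inference", eps=eps, max_iter=256)
                tn = run_inference(s0, ctx, "natural_gradient", eps=eps, max_iter=256)
                gap = max(gap, abs(ta.info_path.total_length - tn.info_path.total_length))
            gaps.append(gap)
        assert gaps[0] >= gaps[1] >= gaps[2]

    def test_unknown_scheme(self, rng):
        with pytest.raises(ValueError):
            run_inference([0.5, 0.5], random_context(rng, 2), scheme="sgd")

    def test_trace_csv_export(self, rng, tmp_path):
        import pandas as pd

        trace = run_inference(random_belief(rng, 3), random_context(rng, 3))
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        df = pd.read_csv(path)
        assert set(df.columns) == {
            "iteration",
            "state",
            "belief",
            "voltage",
            "lfp",
            "cumulative_information_length",
        }
        assert df["iteration"].max() == trace.iterations


class TestSimulatedLFP:
    def test_rows_are_voltage_differences(self, rng):
        trace = run_inference(random_belief(rng, 4), random_context(rng, 4))
        lfp = simulated_lfp(trace)
        assert lfp.shape[0] == trace.beliefs.shape[0] - 1
        np.testing.assert_allclose(lfp, np.diff(trace.voltages, axis=0), atol=1e-12)

    def test_decays_to_zero_at_convergence(self, rng):
        ctx = random_context(rng, 4)
        trace = run_inference(random_belief(rng, 4), ctx, tol=1e-6, max_iter=512)
        assert trace.converged
        lfp = simulated_lfp(trace)
        assert np.abs(lfp[-1]).max() < 1e-4

    def test_stationary_start_is_silent(self, rng):
        ctx = random_context(rng, 4)
        trace = run_inference(exact_posterior(ctx), ctx)
        lfp = simulated_lfp(trace)
        assert lfp.size == 0 or np.abs(lfp).max() < 1e-9

    def test_single_iterate_empty(self, rng):
        ctx = random_context(rng, 4)
        trace = run_inference(exact_posterior(ctx), ctx)
        assert trace.iterations == 0
        assert simulated_lfp(trace).shape == (0, 4)
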