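"""Ground-truth contracts of the synthetic generators."""

import numpy as np
import pytest

from infoflow import (
    MotifSpec,
    conditional_transfer_entropy,
    decompose_and_adjust,
    gen_coupled_markov,
    gen_event_study,
    gen_logistic_pair,
    gen_panel,
    gen_seasonal_counts,
    signed_rank_event_test,
    event_window_rates,
)


class TestCoupledMarkov:
    def test_same_seed_reproduces(self):
        spec = MotifSpec(motif="direct", coupling=0.5, length=500, seed=9)
        a, b = gen_coupled_markov(spec), gen_coupled_markov(spec)
        for key in ("X", "Y", "Z"):
            np.testing.assert_array_equal(a[key], b[key])

    def test_coupling_zero_is_independent(self):
        d = gen_coupled_markov(
            MotifSpec(motif="direct", coupling=0.0, length=100_000, seed=1)
        )
        cte = conditional_transfer_entropy(d["X"], d["Y"], [d["Z"]]).value
        assert cte < 0.001

    def test_coupling_one_direct_is_deterministic_copy(self):
        d = gen_coupled_markov(
            MotifSpec(motif="direct", coupling=1.0, length=20_000, seed=2)
        )
        np.testing.assert_array_equal(d["X"][1:], d["Y"][:-1])
        te = conditional_transfer_entropy(d["X"], d["Y"]).value
        assert te == pytest.approx(np.log2(3), abs=0.01)

    def test_coupling_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="coupling"):
            MotifSpec(motif="direct", coupling=1.2, length=100, seed=0)

    def test_true_links_per_motif(self):
        assert MotifSpec("direct", 0.5, 10, 0).true_links == {("Y", "X")}
        assert MotifSpec("cascade", 0.5, 10, 0).true_links == {("Y", "Z"), ("Z", "X")}
        assert MotifSpec("independent", 0.0, 10, 0).true_links == frozenset()

    def test_marginal_stationarity_split_half(self):
        d = gen_coupled_markov(
            MotifSpec(motif="common_driver", coupling=0.6, length=20_000, seed=3)
        )
        for key in ("X", "Y", "Z"):
            half = len(d[key]) // 2
            f1 = np.bincount(d[key][:half], minlength=3) / half
            f2 = np.bincount(d[key][half:], minlength=3) / half
            assert np.max(np.abs(f1 - f2)) < 0.03

    def test_poisson_emission_variant(self):
        d = gen_coupled_markov(
            MotifSpec(motif="direct", coupling=0.5, length=5000, seed=4,
                      emission="poisson")
        )
        assert "X_counts" in d and d["X_counts"].min() >= 0
        # high hidden state should emit higher counts on average
        hi = d["X_counts"][d["X"] == 2].mean()
        lo = d["X_counts"][d["X"] == 0].mean()
        assert hi > lo


class TestSeasonalCounts:
    def test_truth_components_returned(self):
        s, truth = gen_seasonal_counts(n_days=800, seed=1)
        assert set(truth) == {"trend", "weekly", "yearly", "noise"}
        assert len(s) == 800

    def test_zero_noise_decomposes_cleanly(self):
        s, _ = gen_seasonal_counts(
            weekly_amp=4.0, yearly_amp=0.0, noise_sd=0.0, n_days=1095, seed=2
        )
        adj = decompose_and_adjust(s, periods=(7,))
        assert np.sqrt(np.mean(adj.residuals**2)) < 0.05

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            gen_seasonal_counts(weekly_amp=-1.0, n_days=800, seed=0)

    def test_seeded_reproducibility(self):
        a, _ = gen_seasonal_counts(n_days=760, seed=5)
        b, _ = gen_seasonal_counts(n_days=760, seed=5)
        np.testing.assert_array_equal(a.values, b.values)


class TestLogisticPair:
    def test_unidirectional_truth_label(self):
        _, _, truth = gen_logistic_pair(beta_xy=0.1, beta_yx=0.0, n=300, seed=1)
        assert truth["y_drives_x"] and not truth["x_drives_y"]

    def test_uncoupled_maps_stay_chaotic_in_unit_interval(self):
        x, y, _ = gen_logistic_pair(beta_xy=0.0, beta_yx=0.0, n=2000, seed=2)
        assert np.all((x > 0) & (x < 1)) and np.all((y > 0) & (y < 1))
        assert np.std(x) > 0.1

    def test_divergent_parameters_rejected(self):
        with pytest.raises(ValueError, match="divergent parameters"):
            gen_logistic_pair(r_x=4.5, n=500, seed=3)

    def test_seeded_reproducibility(self):
        a = gen_logistic_pair(n=400, seed=6)[0]
        b = gen_logistic_pair(n=400, seed=6)[0]
        np.testing.assert_array_equal(a, b)


class TestEventStudyGenerator:
    def test_null_study_is_flat(self):
        ev, counts, truth = gen_event_study(
            base_rate=2.0, excitation_height=0.0, n_events=60, seed=1
        )
        assert truth["excitation_height"] == 0.0
        assert counts.mean() == pytest.approx(2.0, rel=0.05)

    def test_power_increases_with_excitation_height(self):
        pvals = []
        for height in (0.0, 0.3, 1.0):
            ps = []
            for s in range(10):
                ev, counts, _ = gen_event_study(
                    base_rate=1.0, excitation_height=height,
                    excitation_minutes=120, n_events=80, seed=300 + s,
                )
                pre, post, _ = event_window_rates(ev, counts, 60)
                ps.append(signed_rank_event_test(pre, post))
            pvals.append(np.median(ps))
        assert pvals[0] > 0.05 > pvals[2]
        assert pvals[2] <= pvals[1]

    def test_span_too_short_rejected(self):
        with pytest.raises(ValueError, match="span too short"):
            gen_event_study(n_events=100, span_minutes=300, seed=0)

    def test_seeded_reproducibility(self):
        a = gen_event_study(n_events=30, seed=8)
        b = gen_event_study(n_events=30, seed=8)
        np.testing.assert_array_equal(a[0].event_times, b[0].event_times)
        np.testing.assert_array_equal(a[1], b[1])


class TestDynamicalPanel:
    def test_shapes_truth_and_determinism(self):
        from infoflow import gen_dynamical_panel

        a, truth = gen_dynamical_panel(n_areas=2, n_days=800, coupling=0.1, seed=5)
        b, _ = gen_dynamical_panel(n_areas=2, n_days=800, coupling=0.1, seed=5)
        assert len(a) == 1 + 3 * 2
        assert truth["true_links"] == {("MPB", "NT")}
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.values, sb.values)

    def test_uncoupled_panel_has_no_links(self):
        from infoflow import gen_dynamical_panel

        _, truth = gen_dynamical_panel(n_areas=1, n_days=800, coupling=0.0, seed=6)
        assert truth["true_links"] == set()

    def test_excessive_coupling_rejected(self):
        from infoflow import gen_dynamical_panel

        with pytest.raises(ValueError, match="coupling"):
            gen_dynamical_panel(coupling=0.7, seed=0)


class TestPanel:
    def test_shapes_and_roles(self):
        series, truth = gen_panel(n_areas=2, n_days=750, seed=1)
        roles = sorted((s.area, s.role) for s in series)
        assert ("", "MPB") in roles
        assert len(series) == 1 + 3 * 2
        assert truth["coupling_mpb_nt"] == 0.0
        assert truth["true_links"] == set()

    def test_coupled_panel_declares_link(self):
        _, truth = gen_panel(n_areas=1, n_days=750, coupling_mpb_nt=0.4, seed=2)
        assert truth["true_links"] == {("MPB", "NT")}

    def test_print_convention_recovers_driver_after_shift(self):
        # raw hidden chains: NT_{t+1} copies h_t exactly at coupling 1
        _, truth = gen_panel(n_areas=1, n_days=750, coupling_mpb_nt=1.0, seed=3)
        h = truth["hidden_mpb"]
        nt = truth["areas"]["area00"]["nt"]
        np.testing.assert_array_equal(nt[1:], h[:-1])
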