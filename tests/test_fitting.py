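"""Parameter recovery, step-count selection, and velocity arithmetic."""

import numpy as np
import pytest

from unwindkit import (
    ProgressCurve,
    Substrate,
    UnwindingMechanism,
    average_replicates,
    closed_form_fraction,
    fit_fixed_n,
    kinetic_step_size,
    mean_step_size,
    select_step_count,
    unwinding_velocity,
)
from unwindkit.fitting import format_step_size, round_half_away
from unwindkit.reference_tables import published_unwinding_parameters
from unwindkit.simulate import FORK_16BP, JUNCTION_16BP


class TestFitFixedN:
    def test_noiseless_self_consistency(self, quench_times):
        truth = UnwindingMechanism(3, 78.4, 12.0)
        curve = ProgressCurve(quench_times, closed_form_fraction(truth, quench_times))
        res = fit_fixed_n(curve, 3)
        assert res.converged
        assert res.k_u_hat == pytest.approx(78.4, rel=1e-4)
        assert res.k_d_hat == pytest.approx(12.0, rel=1e-3)
        assert res.k_u_stderr >= 0 and res.k_d_stderr >= 0

    def test_flat_curve_flagged_degenerate(self):
        curve = ProgressCurve([0.01, 0.02, 0.03, 0.04, 0.05], [0.3] * 5)
        res = fit_fixed_n(curve, 2)
        assert not res.converged
        assert any("degenerate" in f for f in res.flags)

    def test_too_few_points_flagged(self):
        curve = ProgressCurve([0.01, 0.02, 0.03], [0.0, 0.1, 0.2])
        res = fit_fixed_n(curve, 2)
        assert not res.converged

    def test_noisy_recovery_within_ten_percent(self, quench_times):
        truth = UnwindingMechanism(3, 78.4, 46.0)
        rng = np.random.default_rng(42)
        clean = closed_form_fraction(truth, quench_times)
        reps = [
            ProgressCurve(quench_times, np.clip(clean + rng.normal(0, 0.02, clean.size), -0.05, 1.05))
            for _ in range(3)
        ]
        res = fit_fixed_n(average_replicates(reps), 3)
        assert res.converged
        assert abs(res.k_u_hat - 78.4) / 78.4 < 0.10

    def test_deterministic_given_data_and_init(self, quench_times):
        truth = UnwindingMechanism(2, 70.0, 30.0)
        curve = ProgressCurve(quench_times, closed_form_fraction(truth, quench_times))
        r1 = fit_fixed_n(curve, 2, init=(50.0, 10.0))
        r2 = fit_fixed_n(curve, 2, init=(50.0, 10.0))
        assert r1.k_u_hat == r2.k_u_hat and r1.rss == r2.rss


class TestSelectStepCount:
    def test_noiseless_single_step_selected(self, quench_times):
        truth = UnwindingMechanism(1, 50.0, 5.0)
        curve = ProgressCurve(quench_times, closed_form_fraction(truth, quench_times))
        assert select_step_count(curve).n_selected == 1

    def test_junction_like_curve_needs_three_steps(self, quench_times, junction_truth):
        mech, sub = junction_truth
        rng = np.random.default_rng(11)
        clean = closed_form_fraction(mech, quench_times)
        reps = [
            ProgressCurve(quench_times, np.clip(clean + rng.normal(0, 0.02, clean.size), -0.05, 1.05))
            for _ in range(3)
        ]
        res = select_step_count(reps, substrate=sub)
        assert res.n_selected == 3
        assert res.m == pytest.approx(8 / 3)

    def test_fork_like_curve_needs_two_steps(self, quench_times, fork_truth):
        mech, sub = fork_truth
        rng = np.random.default_rng(12)
        clean = closed_form_fraction(mech, quench_times)
        reps = [
            ProgressCurve(quench_times, np.clip(clean + rng.normal(0, 0.02, clean.size), -0.05, 1.05))
            for _ in range(3)
        ]
        res = select_step_count(reps, substrate=sub)
        assert res.n_selected == 2
        assert res.m == pytest.approx(3.0)

    def test_per_n_table_covers_candidates(self, quench_times):
        truth = UnwindingMechanism(2, 70.0, 30.0)
        curve = ProgressCurve(quench_times, closed_form_fraction(truth, quench_times))
        res = select_step_count(curve, range(1, 5))
        assert [row["n"] for row in res.per_n_table] == [1, 2, 3, 4]
        assert any(row["n"] == res.n_selected for row in res.per_n_table)

    def test_invariant_to_time_and_rate_rescaling(self, quench_times):
        truth = UnwindingMechanism(3, 78.4, 46.0)
        rng = np.random.default_rng(3)
        noisy = np.clip(
            closed_form_fraction(truth, quench_times) + rng.normal(0, 0.02, quench_times.size),
            -0.05, 1.05,
        )
        c = 10.0
        res_orig = select_step_count(ProgressCurve(quench_times, noisy))
        res_scaled = select_step_count(ProgressCurve(quench_times / c, noisy))
        assert res_orig.n_selected == res_scaled.n_selected
        assert res_scaled.k_u_hat == pytest.approx(c * res_orig.k_u_hat, rel=1e-6)


class TestStepSizeArithmetic:
    @pytest.mark.parametrize(
        "L,L0,LB,n,expected",
        [(16, 8, 0, 3, 8 / 3), (20, 8, 2, 2, 5.0), (10, 8, 2, 4, 0.0)],
    )
    def test_kinetic_step_size(self, L, L0, LB, n, expected):
        sub = Substrate("s", L=L, L0=L0, LB=LB)
        assert kinetic_step_size(sub, n) == pytest.approx(expected)

    def test_display_truncates_toward_zero(self):
        junction = Substrate("j", L=16, L0=8, LB=0)
        fork = Substrate("f", L=16, L0=8, LB=2)
        assert format_step_size(junction, 3) == "2.66"
        assert format_step_size(fork, 2) == "3"

    @pytest.mark.parametrize(
        "k_u,L,LB,n,expected",
        [
            (71.9, 16, 2, 2, 216),
            (61.9, 20, 2, 2, 310),
            (141.0, 16, 2, 2, 423),
            (78.4, 16, 0, 3, 209),
        ],
    )
    def test_velocity_reproduces_tabulated_values(self, k_u, L, LB, n, expected):
        sub = Substrate("s", L=L, L0=8, LB=LB)
        assert unwinding_velocity(k_u, sub, n, rounded=True) == expected

    def test_velocity_zero_when_nothing_to_unwind(self):
        sub = Substrate("s", L=10, L0=8, LB=2)
        assert unwinding_velocity(100.0, sub, 2) == 0.0

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(309.5) == 310
        assert round_half_away(2.5) == 3
        assert round_half_away(-2.5) == -3


class TestMeanStepSize:
    def test_wild_type_average(self):
        df = published_unwinding_parameters()
        wt = df[(df.dataset == "excess_enzyme") & (df.enzyme == "wtDda")]
        m_values = [row["L"] - row.L0 - row.LB for _, row in wt.iterrows()]
        m_values = [v / n for v, n in zip(m_values, wt.n)]
        mean, sd = mean_step_size(m_values)
        assert round(mean, 1) == 3.4
        assert round(sd, 1) == 0.9

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 6, size=10)
        mean, sd = mean_step_size(list(vals))
        assert mean == pytest.approx(vals.sum() / 10)
        assert sd == pytest.approx(np.sqrt(((vals - vals.mean()) ** 2).sum() / 9))

    def test_identical_values_zero_sd(self):
        assert mean_step_size([3.0, 3.0, 3.0])[1] == 0.0

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            mean_step_size([3.0])


def test_average_replicates_requires_common_grid(quench_times):
    a = ProgressCurve(quench_times, np.zeros_like(quench_times) + 0.1)
    b = ProgressCurve(quench_times * 2, np.zeros_like(quench_times) + 0.1)
    with pytest.raises(ValueError):
        average_replicates([a, b])
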