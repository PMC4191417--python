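"""Two-site fork-binding equilibrium: conservation, limits, crossover."""

import numpy as np
import pytest

from unwindkit import BindingConfig, amplitude_vs_ratio_table, predict_product, solve_equilibrium


def brute_force_free_enzyme(cfg, grid_points=4_000_001):
    """Dense grid scan over E_free for the conservation equation root."""
    x = np.linspace(0.0, cfg.E_total, grid_points)
    th5 = x / (cfg.Kd5 + x)
    th3 = x / (cfg.Kd3 + x) if cfg.substrate_kind == "fork" else 0.0
    resid = x + cfg.D_total * (th5 + th3) - cfg.E_total
    return x[np.argmin(np.abs(resid))]


class TestSolveEquilibrium:
    def test_junction_saturates_under_excess_enzyme(self):
        cfg = BindingConfig(E_total=150, D_total=2, Kd5=1, Kd3=1, substrate_kind="junction")
        st = solve_equilibrium(cfg)
        assert st.D5 / cfg.D_total > 0.99
        assert st.D3 == 0.0 and st.D53 == 0.0

    def test_independent_sites_quarter_doubly_bound_at_kd(self):
        # at E_free == Kd each site is half occupied, so independence gives
        # D53/D_total = 0.25; arrange E_total so that E_free lands at Kd
        kd = 10.0
        d_total = 8.0
        cfg = BindingConfig(E_total=kd + d_total, D_total=d_total, Kd5=kd, Kd3=kd, substrate_kind="fork")
        st = solve_equilibrium(cfg)
        assert st.E_free == pytest.approx(kd, rel=1e-9)
        assert st.D53 / d_total == pytest.approx(0.25, rel=1e-9)

    def test_matches_brute_force_grid(self):
        cfg = BindingConfig(E_total=150, D_total=300, Kd5=10, Kd3=10, substrate_kind="fork")
        st = solve_equilibrium(cfg)
        e_grid = brute_force_free_enzyme(cfg)
        assert st.E_free == pytest.approx(e_grid, abs=1e-4)

    @pytest.mark.parametrize("E,D", [(150, 2), (150, 75), (150, 150), (150, 300), (10, 500), (0, 50)])
    def test_conservation_laws(self, E, D):
        cfg = BindingConfig(E_total=E, D_total=D, Kd5=7.5, Kd3=22.0, substrate_kind="fork")
        st = solve_equilibrium(cfg)
        assert st.D_free + st.D5 + st.D3 + st.D53 == pytest.approx(D, abs=1e-9)
        assert st.E_free + st.D5 + st.D3 + 2 * st.D53 == pytest.approx(E, abs=1e-9)
        for v in (st.E_free, st.D_free, st.D5, st.D3, st.D53):
            assert v >= 0

    def test_junction_is_fork_limit_of_infinite_kd3(self):
        j = solve_equilibrium(BindingConfig(150, 2, Kd5=10, Kd3=10, substrate_kind="junction"))
        f = solve_equilibrium(BindingConfig(150, 2, Kd5=10, Kd3=1e9, substrate_kind="fork"))
        for a, b in zip(
            (j.E_free, j.D_free, j.D5, j.D3, j.D53),
            (f.E_free, f.D_free, f.D5, f.D3, f.D53),
        ):
            assert a == pytest.approx(b, abs=1e-6)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            BindingConfig(E_total=-1, D_total=1, Kd5=1)
        with pytest.raises(ValueError):
            BindingConfig(E_total=1, D_total=1, Kd5=0)
        with pytest.raises(ValueError):
            BindingConfig(E_total=1, D_total=1, Kd5=1, substrate_kind="hairpin")


class TestPredictProduct:
    def test_zero_amplitude_zero_product(self):
        cfg = BindingConfig(150, 2, Kd5=1, Kd3=1, substrate_kind="fork",
                            A_productive_fork=0.0)
        assert solve_equilibrium(cfg).predicted_product == 0.0

    def test_saturated_junction_product_is_amplitude_times_dna(self):
        cfg = BindingConfig(E_total=1.5e6, D_total=2, Kd5=1, substrate_kind="junction",
                            A_productive_junction=0.25)
        st = solve_equilibrium(cfg)
        assert st.predicted_product == pytest.approx(0.5, rel=1e-4)

    def test_junction_product_grows_with_dna_while_fork_is_flat(self):
        # enzyme-limited regime: the junction keeps converting added DNA,
        # the fork wastes enzyme on non-productive 3' arms
        fork_prod, junc_prod = [], []
        for d in (75.0, 150.0, 300.0):
            f = solve_equilibrium(BindingConfig(150, d, Kd5=10, Kd3=10, substrate_kind="fork"))
            j = solve_equilibrium(BindingConfig(150, d, Kd5=10, Kd3=10, substrate_kind="junction"))
            fork_prod.append(f.predicted_product)
            junc_prod.append(j.predicted_product)
        assert junc_prod[0] < junc_prod[1] < junc_prod[2]
        spread = (max(fork_prod) - min(fork_prod)) / max(fork_prod)
        assert spread < 0.25  # near-constant compared to the junction's ~2x growth


class TestAmplitudeVsRatioTable:
    def test_single_point_grid_matches_direct_solve(self):
        cfg = BindingConfig(150, 80, Kd5=10, Kd3=10, substrate_kind="fork")
        table = amplitude_vs_ratio_table(cfg, [80.0])
        st = solve_equilibrium(cfg)
        assert table.loc[0, "E_free_nM"] == pytest.approx(st.E_free)
        assert table.loc[0, "product_nM"] == pytest.approx(st.predicted_product)

    def test_reversed_grid_reverses_rows(self):
        cfg = BindingConfig(150, 80, Kd5=10, Kd3=10, substrate_kind="fork")
        fwd = amplitude_vs_ratio_table(cfg, [75, 150, 300])
        rev = amplitude_vs_ratio_table(cfg, [300, 150, 75])
        assert list(fwd.D_total_nM) == list(reversed(rev.D_total_nM))

    def test_fork_productive_fraction_non_increasing_in_dna(self):
        cfg = BindingConfig(150, 1, Kd5=10, Kd3=10, substrate_kind="fork")
        table = amplitude_vs_ratio_table(cfg, np.linspace(5, 600, 40))
        frac = (table.D5 + table.D53) / table.D_total_nM
        assert np.all(np.diff(frac) <= 1e-12)


def test_amplitude_reversal_between_enzyme_and_substrate_excess():
    """Fork out-produces the junction under excess enzyme; the ordering
    reverses when substrate is in excess."""
    kw = dict(Kd5=10, Kd3=10, A_productive_fork=0.45, A_productive_junction=0.25)
    f_lo = solve_equilibrium(BindingConfig(150, 2, substrate_kind="fork", **kw))
    j_lo = solve_equilibrium(BindingConfig(150, 2, substrate_kind="junction", **kw))
    f_hi = solve_equilibrium(BindingConfig(150, 300, substrate_kind="fork", **kw))
    j_hi = solve_equilibrium(BindingConfig(150, 300, substrate_kind="junction", **kw))
    assert f_lo.predicted_product > j_lo.predicted_product
    assert j_hi.predicted_product > f_hi.predicted_product
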