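import numpy as np
import pytest

import _oracles as oracle
from ecoclim import indices as ix
from ecoclim.climate_io import GridDefinition, MonthlyClimatology
from ecoclim.phenoclim import WEEK_DAYS, soil_moisture_balance, to_weekly
from conftest import random_weekly


@pytest.mark.parametrize(
    "t, expected",
    [(26.0, 1.0), (19.0, 0.0), (32.0, 0.5), (18.0, 0.0), (36.0, 0.0), (24.0, 1.0), (21.5, 0.5)],
)
def test_temperature_trapezoid(preset, t, expected):
    assert ix.temperature_index(t, preset) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "sm, expected",
    [(1.0, 1.0), (0.4, 0.0), (1.8, 0.5), (0.5, 0.5), (2.0, 0.0), (2.5, 0.0)],
)
def test_moisture_trapezoid(preset, sm, expected):
    assert ix.moisture_index(sm, preset) == pytest.approx(expected, abs=1e-12)


def test_annual_growth_index_hand_values():
    assert ix.annual_growth_index(np.ones(52)) == 100.0
    assert ix.annual_growth_index(np.zeros(52)) == 0.0
    gi = np.zeros(52)
    gi[:26] = 1.0
    assert ix.annual_growth_index(gi) == pytest.approx(50.0, rel=1e-12)


class TestStressHandChecks:
    """Frozen hand accumulations with the published rates."""

    def test_cold_stress_zero_when_thresholds_never_crossed(self, preset):
        assert ix.cold_stress(np.full(52, 15.0), np.full(52, 20.0), preset) == 0.0

    def test_cold_stress_four_cold_weeks(self, preset):
        t_min = np.full(52, 20.0)
        t_min[:4] = 10.0  # deficit 5 °C for 4 weeks
        cs = ix.cold_stress(t_min, np.full(52, 100.0), preset)
        assert cs == pytest.approx(100 * 0.005 * 5 * 4, rel=1e-12)  # = 10

    def test_cold_stress_degree_day_mechanism(self, preset):
        cs = ix.cold_stress(np.full(52, 20.0), np.zeros(52), preset)
        assert cs == pytest.approx(100 * 0.0005 * 20 * 52, rel=1e-12)  # = 52

    def test_heat_stress_values(self, preset):
        assert ix.heat_stress(np.full(52, 36.0), preset) == 0.0
        t_max = np.full(52, 30.0)
        t_max[10] = 38.0
        assert ix.heat_stress(t_max, preset) == pytest.approx(0.2, rel=1e-12)
        assert ix.heat_stress(np.full(52, 46.0), preset) == pytest.approx(52.0, rel=1e-12)

    def test_dry_stress_values(self, preset):
        assert ix.dry_stress(np.full(52, 0.4), preset) == 0.0
        assert ix.dry_stress(np.full(52, 0.2), preset) == pytest.approx(7.28, rel=1e-12)
        assert ix.dry_stress(np.full(52, 0.0), preset) == pytest.approx(14.56, rel=1e-12)

    def test_wet_stress_values(self, preset):
        assert ix.wet_stress(np.full(52, 2.0), preset) == 0.0
        assert ix.wet_stress(np.full(52, 0.8), preset) == 0.0
        assert ix.wet_stress(np.full(52, 2.5), preset) == pytest.approx(5.98, rel=1e-12)


class TestEcoclimaticIndex:
    def test_identity_under_zero_stress(self, preset):
        assert ix.ecoclimatic_index(80.0, 0, 0, 0, 0, 1500.0, preset) == 80.0

    @pytest.mark.parametrize("stress", ["cs", "hs", "ds", "ws"])
    def test_total_stress_annihilates(self, preset, stress):
        kw = {"cs": 0.0, "hs": 0.0, "ds": 0.0, "ws": 0.0, stress: 100.0}
        ei = ix.ecoclimatic_index(80.0, kw["cs"], kw["hs"], kw["ds"], kw["ws"], 2000.0, preset)
        assert ei == 0.0

    def test_hand_product(self, preset):
        ei = ix.ecoclimatic_index(50.0, 20.0, 10.0, 0.0, 0.0, 2000.0, preset)
        assert ei == pytest.approx(36.0, rel=1e-12)

    def test_degree_day_gate(self, preset):
        assert ix.ecoclimatic_index(80.0, 0, 0, 0, 0, 1499.9, preset) == 0.0


def test_degree_days_use_week_lengths(preset):
    dd = ix.degree_days(np.full(52, 20.0), preset)  # 1 °C above DV0
    np.testing.assert_allclose(dd, WEEK_DAYS)
    assert ix.degree_days(np.full(52, 10.0), preset).sum() == 0.0


def test_accumulators_match_literal_loop_oracle_exactly(preset):
    """Vectorized stress/degree-day reductions are bit-identical to a
    plain per-cell Python loop over the 52 weeks (1 000 random series)."""
    rng = np.random.default_rng(1234)
    wk = random_weekly(rng, 1000)
    sm_series = rng.uniform(0.0, 2.5, (52, 1000))
    dd = ix.degree_days(wk.t_avg, preset)
    cs = ix.cold_stress(wk.t_min, dd, preset)
    hs = ix.heat_stress(wk.t_max, preset)
    ds = ix.dry_stress(sm_series, preset)
    ws = ix.wet_stress(sm_series, preset)
    annual_dd = ix._weekly_sum(dd)
    for c in range(1000):
        t_min = [float(x) for x in wk.t_min[:, c]]
        t_max = [float(x) for x in wk.t_max[:, c]]
        t_avg = [float(x) for x in wk.t_avg[:, c]]
        sm = [float(x) for x in sm_series[:, c]]
        dd_c = oracle.degree_days(t_avg, preset.DV0)
        assert cs[c] == oracle.cold_stress(t_min, dd_c, preset)
        assert hs[c] == oracle.heat_stress(t_max, preset)
        assert ds[c] == oracle.dry_stress(sm, preset)
        assert ws[c] == oracle.wet_stress(sm, preset)
        acc = 0.0
        for v in dd_c:
            acc = acc + v
        assert annual_dd[c] == acc


def test_full_cell_pipeline_matches_oracle_composition(preset):
    """GIA and EI agree with the literal-loop composition to 1e-14."""
    rng = np.random.default_rng(99)
    wk = random_weekly(rng, 50)
    smres = soil_moisture_balance(wk, preset)
    out = ix.run_weekly(wk, smres, preset)
    for c in range(50):
        ti = [oracle.trapezoid(float(t), preset.DV0, preset.DV1, preset.DV2, preset.DV3)
              for t in wk.t_avg[:, c]]
        mi = [oracle.trapezoid(float(s), preset.SM0, preset.SM1, preset.SM2, preset.SM3)
              for s in smres.sm[:, c]]
        gia = oracle.annual_growth_index(ti, mi)
        dd = oracle.degree_days([float(t) for t in wk.t_avg[:, c]], preset.DV0)
        cs = oracle.cold_stress([float(t) for t in wk.t_min[:, c]], dd, preset)
        hs = oracle.heat_stress([float(t) for t in wk.t_max[:, c]], preset)
        ds = oracle.dry_stress([float(s) for s in smres.sm[:, c]], preset)
        ws = oracle.wet_stress([float(s) for s in smres.sm[:, c]], preset)
        ei = oracle.ecoclimatic_index(gia, cs, hs, ds, ws, sum(dd), preset)
        assert out["gia"][c] == pytest.approx(gia, rel=1e-14, abs=1e-14)
        assert out["ei"][c] == pytest.approx(ei, rel=1e-13, abs=1e-13)


def test_ei_bounded_under_fuzzing(preset):
    rng = np.random.default_rng(2024)
    wk = random_weekly(rng, 2000)
    smres = soil_moisture_balance(wk, preset)
    out = ix.run_weekly(wk, smres, preset)
    assert np.all(out["ei"] >= 0.0) and np.all(out["ei"] <= 100.0)
    assert np.all(out["gia"] >= 0.0) and np.all(out["gia"] <= 100.0)
    for k in ("cs", "hs", "ds", "ws"):
        assert np.all(out[k] >= 0.0) and np.all(out[k] <= 100.0)


def test_ei_equals_gia_when_stress_free(preset):
    """With all stress rates zeroed and no degree-day requirement, EI = GIA."""
    import dataclasses

    free = dataclasses.replace(preset, THCS=-1e-300, DHCS=-1e-300, HDS=-1e-300,
                               THHS=1e-300, HWS=1e-300, PDD=0.0)
    rng = np.random.default_rng(7)
    wk = random_weekly(rng, 200)
    smres = soil_moisture_balance(wk, free)
    out = ix.run_weekly(wk, smres, free)
    np.testing.assert_array_equal(out["ei"], out["gia"])


def test_increasing_stress_rate_never_raises_ei(preset):
    rng = np.random.default_rng(3)
    wk = random_weekly(rng, 300)
    smres = soil_moisture_balance(wk, preset)
    base = ix.run_weekly(wk, smres, preset)["ei"]
    harsher = preset.replace(THCS=-0.01, HDS=-0.014, THHS=0.002, HWS=0.0046, DHCS=-0.001)
    worse = ix.run_weekly(wk, smres, harsher)["ei"]
    assert np.all(worse <= base + 1e-12)


def test_warming_never_decreases_heat_stress_above_threshold(preset):
    rng = np.random.default_rng(4)
    t_max = rng.uniform(36.0, 45.0, (52, 100))
    assert np.all(ix.heat_stress(t_max + 2.0, preset) >= ix.heat_stress(t_max, preset))


def test_grid_run_equals_per_cell_runs(preset):
    from ecoclim.synthetic import SyntheticSpec, make_climatology

    clim = make_climatology(SyntheticSpec(n_lat=3, n_lon=4, seed=5))
    grid_res = ix.run_grid(clim, preset)
    for i in range(3):
        for j in range(4):
            g1 = GridDefinition(float(clim.grid.lons[j]), float(clim.grid.lats[i]),
                                clim.grid.cell_size, 1, 1)
            cell = MonthlyClimatology(
                g1,
                *(getattr(clim, v)[:, i:i + 1, j:j + 1] for v in
                  ("tmin", "tmax", "ptotal", "rh0900", "rh1500")),
            )
            single = ix.run_cell(cell, preset)
            assert single.ei[0, 0] == grid_res.ei[i, j]
            assert single.cls[0, 0] == grid_res.cls[i, j]


def test_cold_constant_cell_is_unsuitable(preset):
    """Year-round 15 °C mean: no degree-days, no growth, EI = 0."""
    grid = GridDefinition(0.0, 0.0, n_lon=1, n_lat=1)
    shape = (12, 1, 1)
    clim = MonthlyClimatology(grid, np.full(shape, 11.0), np.full(shape, 19.0),
                              np.full(shape, 150.0), np.full(shape, 80.0), np.full(shape, 70.0))
    res = ix.run_cell(clim, preset)
    assert res.annual_dd[0, 0] == 0.0
    assert res.ei[0, 0] == 0.0
    assert res.cls[0, 0] == ix.SuitabilityClass.UNSUITABLE


def test_masked_cells_propagate(preset):
    from ecoclim.synthetic import SyntheticSpec, make_climatology

    clim = make_climatology(SyntheticSpec(n_lat=3, n_lon=3, seed=1))
    mask = clim.mask.copy()
    mask[1, 1] = False
    clim2 = MonthlyClimatology(clim.grid, clim.tmin, clim.tmax, clim.ptotal,
                               clim.rh0900, clim.rh1500, mask=mask)
    res = ix.run_grid(clim2, preset)
    assert np.isnan(res.ei[1, 1]) and not res.mask[1, 1]
    assert np.isfinite(res.ei[0, 0])
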