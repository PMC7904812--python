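"""Discounted cash-flow engine vs closed-form oracles; map products."""

import math

import numpy as np
import pytest
from scipy.optimize import bisect

import carbonprospect as cp


def annuity(n: int, r: float) -> float:
    return (1 - (1 + r) ** -n) / r


def npv_closed_form(flux_fast: float, area: float,
                    p: cp.FinanceParams) -> float:
    """Independent geometric-series NPV for a belowground-free cell.

    NPV = -E + price0*flux*[a(f, r) + (1+r)^-f * x(1-x^(H-f))/(1-x)]
          - M*a(H, r),  with x = (1+g)/(1+r).
    """
    r, g, f, H = p.discount, p.appreciation, p.flat_years, p.horizon
    x = (1 + g) / (1 + r)
    rev_factor = annuity(f, r) + (1 + r) ** -f * x * (1 - x ** (H - f)) / (1 - x)
    m = p.cost_multiplier
    return (-p.establishment_cost * m * area
            + p.price0 * flux_fast * rev_factor
            - p.maintenance_cost * m * area * annuity(H, r))


class TestPriceSchedule:
    def test_flat_then_appreciating(self):
        p = cp.FinanceParams()
        assert cp.price_at_year(3, p) == 5.8
        assert cp.price_at_year(5, p) == 5.8
        assert cp.price_at_year(6, p) == pytest.approx(5.8 * 1.05, abs=1e-12)
        assert cp.price_at_year(30, p) == pytest.approx(5.8 * 1.05 ** 25, abs=1e-12)

    def test_out_of_range_year_rejected(self):
        with pytest.raises(ValueError):
            cp.price_at_year(0)
        with pytest.raises(ValueError):
            cp.price_at_year(31)


class TestEngineVsClosedForm:
    def test_zero_flux_npv_is_pv_of_costs(self):
        p = cp.FinanceParams()
        expected = -(25 + 10 * annuity(30, 0.10))
        got = cp.npv_per_cell(0.0, 0.0, 1.0, p)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(-119.27, abs=5e-3)

    def test_engine_matches_geometric_series_on_random_draws(self, rng):
        """Year-loop NPV vs closed form, 1000 random parameter draws."""
        for _ in range(1000):
            p = cp.FinanceParams(
                establishment_cost=rng.uniform(0, 100),
                maintenance_cost=rng.uniform(0, 50),
                price0=rng.uniform(0.5, 100),
                flat_years=int(rng.integers(1, 10)),
                appreciation=rng.uniform(0.0, 0.15),
                horizon=int(rng.integers(10, 40)),
                discount=rng.uniform(0.02, 0.3),
                cost_multiplier=rng.uniform(1.0, 2.0),
            )
            flux = rng.uniform(0, 10)
            area = rng.uniform(0.5, 200)
            got = cp.npv_per_cell(flux, 0.0, area, p)
            want = npv_closed_form(flux, area, p)
            assert got == pytest.approx(want, rel=1e-9, abs=1e-9)

    def test_break_even_flux_matches_bisection(self):
        """Under defaults, NPV(flux) crosses zero near 1.61 tCO2/ha/yr."""
        p = cp.FinanceParams()
        f = lambda flux: cp.npv_per_cell(flux, 0.0, 1.0, p)
        root = bisect(f, 0.0, 100.0, xtol=1e-12)
        closed = (25 + 10 * annuity(30, 0.1)) / (
            npv_closed_form(1.0, 0.0, p) - npv_closed_form(0.0, 0.0, p))
        assert root == pytest.approx(closed, abs=1e-6)
        assert root == pytest.approx(1.61, abs=5e-3)

    def test_revenue_linearity_in_flux(self):
        p = cp.FinanceParams()
        cost_pv = -cp.npv_per_cell(0.0, 0.0, 3.0, p)
        n1 = cp.npv_per_cell(2.0, 1.0, 3.0, p)
        n2 = cp.npv_per_cell(4.0, 2.0, 3.0, p)
        assert n2 + cost_pv == pytest.approx(2 * (n1 + cost_pv), rel=1e-12)

    def test_npv_affine_and_increasing_in_price(self):
        p = cp.FinanceParams()
        vals = [cp.npv_per_cell(1.0, 0.5, 1.0, p.with_price0(q))
                for q in (2.0, 4.0, 6.0)]
        assert vals[2] - vals[1] == pytest.approx(vals[1] - vals[0], rel=1e-9)
        assert vals[0] < vals[1] < vals[2]

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            cp.npv_per_cell(-1.0, 0.0, 1.0)


class TestBreakEvenPrice:
    def test_self_consistency_at_break_even(self):
        p = cp.FinanceParams()
        # pick a flux and find the price that zeroes NPV
        be = cp.break_even_price0(2.0, 0.7, 1.0, p)
        assert cp.npv_per_cell(2.0, 0.7, 1.0, p.with_price0(be)) == pytest.approx(
            0.0, abs=1e-9)
        # a cell exactly at break-even under defaults returns price0
        flux = cp.break_even_price0(1.0, 0.0, 1.0, p) / 5.8
        be2 = cp.break_even_price0(1.0 * flux, 0.0, 1.0, p)
        assert be2 == pytest.approx(5.8, abs=1e-9)

    def test_npv_changes_sign_around_break_even(self):
        p = cp.FinanceParams()
        be = cp.break_even_price0(1.5, 0.3, 2.0, p)
        eps = 1e-6 * be
        assert cp.npv_per_cell(1.5, 0.3, 2.0, p.with_price0(be + eps)) > 0
        assert cp.npv_per_cell(1.5, 0.3, 2.0, p.with_price0(be - eps)) < 0

    def test_matches_bisection_oracle(self, rng):
        p = cp.FinanceParams()
        for _ in range(50):
            ff, fs, a = rng.uniform(0.1, 5), rng.uniform(0, 2), rng.uniform(0.5, 50)
            be = cp.break_even_price0(ff, fs, a, p)
            f = lambda q: cp.npv_per_cell(ff, fs, a, p.with_price0(q))
            root = bisect(f, 1e-9, 1e6, xtol=1e-9)
            assert be == pytest.approx(root, rel=1e-6)

    def test_zero_flux_never_viable(self):
        assert cp.break_even_price0(0.0, 0.0, 1.0) == math.inf


class TestNPVMap:
    def test_all_zero_flux_world_has_no_viable_cells(self, small_world):
        g = small_world.grid
        zeros = cp.RasterLayer(g, np.zeros(g.shape))
        pools = cp.build_pool_stack(small_world.agb, small_world.agb_sd,
                                    small_world.soc)
        elig = cp.eligibility_mask(small_world.landcover,
                                   small_world.eligibility_config())
        inv = cp.certify(pools, zeros, elig, small_world.area())
        nmap = cp.npv_map(inv, small_world.area())
        assert nmap.viable.values.sum() == 0.0

    def test_uniform_flux_above_break_even_fully_viable(self, small_world):
        res = cp.run_pipeline(small_world)
        inv = res.investible
        # push every eligible cell far above break-even
        boosted = inv.scaled(1e3)
        nmap = cp.npv_map(boosted, small_world.area())
        elig = res.eligibility.values > 0
        pos = boosted.flux_total().central.values > 0
        assert (nmap.viable.values[pos] == 1).all()
        assert (nmap.viable.values[~elig] == 0).all()

    def test_per_cell_equality_with_scalar_engine(self, result200, rng):
        inv, area, nmap = (result200.investible, result200.area, result200.npv)
        rows = rng.integers(0, inv.grid.n_rows, 100)
        cols = rng.integers(0, inv.grid.n_cols, 100)
        for i, j in zip(rows, cols):
            want = cp.npv_per_cell(inv.flux_fast.central.values[i, j],
                                   inv.flux_slow.central.values[i, j],
                                   area.values[i, j])
            assert nmap.npv_total.central.values[i, j] == pytest.approx(
                want, rel=1e-12, abs=1e-9)

    def test_viable_iff_break_even_at_most_price0(self, result200):
        nmap = result200.npv
        pos = result200.investible.flux_total().central.values > 0
        viable = nmap.viable.values > 0
        below = nmap.break_even_price0.values < 5.8
        assert (viable[pos] == below[pos]).all()

    def test_viable_only_masks_unprofitable_cells(self, result200):
        cut = result200.npv.viable_only()
        assert (cut.central.values[cut.central.mask] > 0).all()


class TestPriceSweep:
    def test_fractions_match_break_even_shares(self, result200):
        """Sweep fraction at p == carbon share of cells with NPV(p) > 0."""
        inv, area = result200.investible, result200.area
        sweep = result200.sweep
        total = inv.flux_total().central.values
        be = result200.npv.break_even_price0.values
        pos = total > 0
        for _, row in sweep.iterrows():
            p = row["price0"]
            viable = pos & (be < p)  # NPV(p) > 0 <=> be < p (ties non-viable)
            want_c = total[viable].sum() / total[pos].sum()
            want_a = (area.values[viable].sum() / area.values[pos].sum())
            assert row["viable_carbon_fraction"] == pytest.approx(want_c, abs=1e-12)
            assert row["viable_area_fraction"] == pytest.approx(want_a, abs=1e-12)

    def test_fractions_monotone_and_saturating(self, result200):
        f = result200.sweep["viable_carbon_fraction"].to_numpy()
        assert (np.diff(f) >= 0).all()
        assert f[-1] <= 1.0

    def test_vanishing_price_kills_viability(self, result200):
        inv, area = result200.investible, result200.area
        df = cp.price_sweep(inv, area, price_grid=(1e-9,))
        assert df["viable_carbon_fraction"].iloc[0] == 0.0

    def test_invalid_grid_rejected(self, result200):
        with pytest.raises(ValueError):
            cp.price_sweep(result200.investible, result200.area, price_grid=())
        with pytest.raises(ValueError):
            cp.price_sweep(result200.investible, result200.area,
                           price_grid=(5.0, 1.0))


class TestAccumulationCurve:
    def test_final_value_equals_aggregate_viable_npv(self, small_result):
        inv, area, nmap = (small_result.investible, small_result.area,
                           small_result.npv)
        curve = cp.accumulation_curve(inv, area)
        viable = nmap.viable.values > 0
        for name in ("low", "central", "high"):
            track = curve[(curve["track"] == name)
                          & (curve["year"] == 30)]["cumulative_profit"].iloc[0]
            layer = getattr(nmap.npv_total, name)
            want = layer.values[viable & layer.mask].sum()
            assert track == pytest.approx(want, rel=1e-6)

    def test_single_cell_curve_matches_scalar_cashflows(self):
        g = cp.GridSpec(0.0, 1.0, 0.5, 1, 1)
        mk = lambda v, u="": cp.RasterLayer(g, np.asarray([[v]], float), units=u)
        triple = lambda v: cp.Triple(mk(v), mk(v), mk(v))
        inv = cp.InvestibleFlux(flux_fast=triple(300.0), flux_slow=triple(50.0),
                                density_fast=triple(3.0), density_slow=triple(0.5),
                                eligibility=mk(1.0), params=cp.CertParams())
        area = mk(100.0, "ha")
        p = cp.FinanceParams()
        curve = cp.accumulation_curve(inv, area, p)
        central = curve[curve["track"] == "central"]
        cum = -25.0 * 100.0
        got = central.sort_values("year")["cumulative_profit"].to_numpy()
        assert got[0] == pytest.approx(cum)
        for t in range(1, 31):
            q = 300.0 + 50.0 * min(t, 10) / 10.0
            cum += (cp.price_at_year(t, p) * q - 10.0 * 100.0) / 1.1 ** t
            assert got[t] == pytest.approx(cum, rel=1e-12)

    def test_flat_curve_iff_zero_cash_flows(self):
        g = cp.GridSpec(0.0, 1.0, 0.5, 1, 1)
        mk = lambda v: cp.RasterLayer(g, np.asarray([[v]], float))
        triple = lambda v: cp.Triple(mk(v), mk(v), mk(v))
        inv = cp.InvestibleFlux(flux_fast=triple(0.0), flux_slow=triple(0.0),
                                density_fast=triple(0.0), density_slow=triple(0.0),
                                eligibility=mk(1.0), params=cp.CertParams())
        p = cp.FinanceParams(establishment_cost=0.0, maintenance_cost=0.0)
        curve = cp.accumulation_curve(inv, mk(1.0), p)
        assert (curve["cumulative_profit"] == 0.0).all()
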