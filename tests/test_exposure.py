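"""Nested Monte Carlo exposure engine: arithmetic, distributions, determinism."""

import numpy as np
import pytest

from cumrisk.exposure import (
    BootstrapResidue,
    EngineConfig,
    FixedResidue,
    PopulationGroup,
    characterize_risk,
    run_two_dimensional,
    sample_inner_loop,
    _group_stream,
)
from cumrisk.rpf import ToxProfile

TOX = [ToxProfile("metalaxyl-M", 8.0), ToxProfile("azoxystrobin", 18.2, is_index=True)]
REF_DOSE = 18.2 / 100  # mg/kg bw/day


def _group(bw=60.0, bw_cv=0.0, consumption=None, gid="g"):
    return PopulationGroup(
        group_id=gid, region="urban", sex="male", age_class="30-44 y",
        bw_mean=bw, bw_cv=bw_cv,
        consumption=consumption or {"Soy sauce": (100.0, 0.0)},
    )


class TestInnerLoop:
    def test_point_mass_diet_gives_exact_arithmetic(self):
        rng = np.random.default_rng(0)
        samples = sample_inner_loop(_group(), {"Soy sauce": 0.867}, 50, rng)
        expected = 0.1 * 0.867 / 60.0
        assert all(s.e_total == pytest.approx(expected, rel=1e-12) for s in samples)

    def test_zero_consumption_gives_zero_exposure(self):
        rng = np.random.default_rng(0)
        g = _group(consumption={"Soy sauce": (0.0, 0.5)})
        samples = sample_inner_loop(g, {"Soy sauce": 0.867}, 20, rng)
        assert all(s.e_total == 0.0 for s in samples)

    def test_lognormal_consumption_mean_matches_closed_form(self):
        # E = CONS/1000 * C / bw with CONS ~ lognormal(mean m, cv): the
        # closed-form mean of E is m*C/(1000*bw)
        m, cv, c, bw, n = 150.0, 0.6, 0.5, 60.0, 20000
        g = _group(bw=bw, consumption={"x": (m, cv)})
        samples = sample_inner_loop(g, {"x": c}, n, np.random.default_rng(1))
        e = np.array([s.e_total for s in samples])
        true_mean = m / 1000 * c / bw
        se = e.std(ddof=1) / np.sqrt(n)
        assert abs(e.mean() - true_mean) < 3 * se

    def test_category_components_sum_to_total(self):
        g = _group(consumption={"a": (100.0, 0.4), "b": (50.0, 0.2)}, bw_cv=0.1)
        samples = sample_inner_loop(g, {"a": 0.5, "b": 0.2}, 200, np.random.default_rng(2))
        for s in samples:
            assert sum(s.e_by_category.values()) == pytest.approx(s.e_total, rel=1e-9)
            assert sum(s.e_by_compound.values()) == pytest.approx(s.e_total, rel=1e-9)
            assert all(v >= 0 for v in s.e_by_category.values())


class TestRiskCharacterization:
    def test_reference_point_mass_risk(self):
        samples = sample_inner_loop(_group(), {"Soy sauce": 0.867}, 1, np.random.default_rng(0))
        r = characterize_risk(samples[0], TOX)
        assert r == pytest.approx(100 * (0.1 * 0.867 / 60.0) / REF_DOSE, rel=1e-12)
        assert r == pytest.approx(0.794, abs=0.0005)

    def test_zero_and_threshold_exposure(self):
        assert characterize_risk(0.0, TOX) == 0.0
        assert characterize_risk(REF_DOSE, TOX) == pytest.approx(100.0, rel=1e-12)

    def test_uf_one_noael_exposure_is_100_percent(self):
        tox = [ToxProfile("i", 18.2, is_index=True, uf_interspecies=1.0, uf_intraspecies=1.0)]
        assert characterize_risk(18.2, tox) == pytest.approx(100.0, rel=1e-12)


class TestTwoDimensional:
    def test_degenerate_inputs_collapse_to_single_value(self):
        cfg = EngineConfig(n_inner=100, n_outer=3, seed=0, outer_uncertainty="sampling-only")
        [res] = run_two_dimensional([_group()], {"Soy sauce": 0.867}, TOX, cfg)
        expected = 100 * (0.1 * 0.867 / 60.0) / REF_DOSE
        for point, lo, hi in res.percentiles.values():
            assert point == pytest.approx(expected, rel=1e-12)
            assert lo == pytest.approx(expected, rel=1e-12)
            assert hi == pytest.approx(expected, rel=1e-12)

    def test_percentile_ordering_and_band_containment(self):
        g = _group(bw_cv=0.15, consumption={"a": (200.0, 0.5), "b": (30.0, 0.8)})
        cfg = EngineConfig(n_inner=500, n_outer=20, seed=3)
        [res] = run_two_dimensional([g], {"a": 0.4, "b": 0.9}, TOX, cfg)
        p = res.percentiles
        for label, (point, lo, hi) in p.items():
            assert lo <= point <= hi
        assert p["P50"][0] <= p["P97.5"][0] <= p["P99.9"][0]

    def test_lognormal_exposure_p975_matches_closed_form(self):
        # exposure exactly lognormal: single category, lognormal consumption,
        # fixed bw and residue; no outer uncertainty
        m, cv, c, bw = 100.0, 0.5, 0.867, 60.0
        sigma = np.sqrt(np.log1p(cv**2))
        mu = np.log(m / 1000 * c / bw) - sigma**2 / 2
        true_p975 = 100 * np.exp(mu + 1.959964 * sigma) / REF_DOSE
        g = _group(bw=bw, consumption={"x": (m, cv)})
        estimates = []
        for rep in range(50):
            rng = _group_stream(17, "g", rep)
            samples = sample_inner_loop(g, {"x": c}, 2000, rng)
            risks = [characterize_risk(s, TOX) for s in samples]
            estimates.append(np.percentile(risks, 97.5))
        estimates = np.array(estimates)
        se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - true_p975) < 3 * se

    def test_doubling_body_weight_halves_risk(self):
        cons = {"a": (200.0, 0.5), "b": (30.0, 0.8)}
        cfg = EngineConfig(n_inner=2000, n_outer=20, seed=5)
        [light] = run_two_dimensional([_group(bw=30.0, bw_cv=0.1, consumption=cons, gid="x")],
                                      {"a": 0.4, "b": 0.9}, TOX, cfg)
        [heavy] = run_two_dimensional([_group(bw=60.0, bw_cv=0.1, consumption=cons, gid="x")],
                                      {"a": 0.4, "b": 0.9}, TOX, cfg)
        for label in light.percentiles:
            ratio = light.percentiles[label][0] / heavy.percentiles[label][0]
            assert ratio == pytest.approx(2.0, rel=1e-9)  # common random numbers

    def test_monotone_in_consumption_mean_under_common_seeds(self):
        cfg = EngineConfig(n_inner=500, n_outer=10, seed=9)
        results = []
        for m in (100.0, 150.0):
            g = _group(bw_cv=0.1, consumption={"a": (m, 0.5)}, gid="x")
            [res] = run_two_dimensional([g], {"a": 0.5}, TOX, cfg)
            results.append(res)
        for label in results[0].percentiles:
            assert results[1].percentiles[label][0] >= results[0].percentiles[label][0]

    def test_hr_basis_dominates_stmr_basis(self, category_residues, tox):
        from cumrisk.rpf import cumulate_categories
        cons = {c: (100.0, 0.4) for c in {r.category for r in category_residues}}
        g = _group(bw_cv=0.1, consumption=cons, gid="x")
        cfg = EngineConfig(n_inner=500, n_outer=10, seed=2)
        points = {}
        for basis in ("stmr", "hr"):
            cats = cumulate_categories(category_residues, tox, basis=basis)
            model = {c: ic.c_index for c, ic in cats.items()}
            [res] = run_two_dimensional([g], model, tox, cfg)
            points[basis] = res.percentiles
        for label in points["stmr"]:
            assert points["hr"][label][0] >= points["stmr"][label][0]

    def test_band_width_shrinks_with_more_replicates(self):
        g = _group(bw_cv=0.15, consumption={"a": (150.0, 0.6)})
        widths = []
        for n_inner, n_outer in [(200, 10), (800, 40), (3200, 160)]:
            cfg = EngineConfig(n_inner=n_inner, n_outer=n_outer, seed=21,
                               outer_uncertainty="sampling-only")
            [res] = run_two_dimensional([g], {"a": 0.5}, TOX, cfg)
            point, lo, hi = res.percentiles["P97.5"]
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]


class TestDeterminism:
    def test_identical_seed_gives_identical_summaries(self):
        g1 = _group(bw_cv=0.1, consumption={"a": (100.0, 0.5)}, gid="g1")
        g2 = _group(bw=30, bw_cv=0.1, consumption={"a": (80.0, 0.5)}, gid="g2")
        cfg = EngineConfig(n_inner=300, n_outer=5, seed=42)
        a = run_two_dimensional([g1, g2], {"a": 0.5}, TOX, cfg)
        b = run_two_dimensional([g1, g2], {"a": 0.5}, TOX, cfg)
        assert a == b

    def test_group_order_does_not_change_results(self):
        g1 = _group(bw_cv=0.1, consumption={"a": (100.0, 0.5)}, gid="g1")
        g2 = _group(bw=30, bw_cv=0.1, consumption={"a": (80.0, 0.5)}, gid="g2")
        cfg = EngineConfig(n_inner=300, n_outer=5, seed=42)
        fwd = {r.group_id: r for r in run_two_dimensional([g1, g2], {"a": 0.5}, TOX, cfg)}
        rev = {r.group_id: r for r in run_two_dimensional([g2, g1], {"a": 0.5}, TOX, cfg)}
        assert fwd == rev


class TestBootstrapResidue:
    def test_bootstrap_draws_come_from_pool(self):
        pool = np.array([0.1, 0.5, 1.0])
        model = BootstrapResidue(pools={"a": pool})
        rng = np.random.default_rng(0)
        draws = model.draw(500, rng)
        assert set(np.unique(draws)) <= set(pool)

    def test_outer_resample_changes_pool_but_not_support(self):
        pool = np.arange(1.0, 9.0)
        model = BootstrapResidue(pools={"a": pool})
        re = model.resample(np.random.default_rng(1))
        assert len(re.pools["a"]) == len(pool)
        assert set(re.pools["a"]) <= set(pool)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EngineConfig(n_inner=0)
        with pytest.raises(ValueError):
            EngineConfig(ci="three-sided")
        with pytest.raises(ValueError):
            EngineConfig(bw_family="cauchy")
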