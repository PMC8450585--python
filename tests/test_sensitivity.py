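"""DSA tornado, PSA distributions, and acceptability curves."""

from dataclasses import replace

import numpy as np
import pytest

from lncea import (
    STRATEGIES,
    ParameterError,
    build_distributions,
    build_model,
    ceac,
    default_wtp_grid,
    enumerate_parameters,
    net_monetary_benefit,
    one_way_dsa,
    run_psa,
    simulate,
    accumulate,
)
from lncea.sensitivity import DistributionSpec, ParameterRef, _pair_icer, tornado_table


@pytest.fixture(scope="module")
def base_icer(params):
    return _pair_icer(params, STRATEGIES["S3"], STRATEGIES["S1"])


class TestDSA:
    def test_degenerate_bounds_reproduce_base_icer(self, params, base_icer):
        ref = ParameterRef(
            "transitions.maintenance.AZA.esrd", 0.0030, 0.0030, 0.0030, "transition"
        )
        (res,) = one_way_dsa(params, parameters=[ref])
        assert res.icer_at_low == pytest.approx(base_icer, rel=1e-12)
        assert res.icer_at_high == pytest.approx(base_icer, rel=1e-12)
        assert res.spread == 0.0

    def test_aza_esrd_moves_icer_monotonically(self, params):
        grid = [0.0006, 0.0030, 0.0090, 0.0160]
        icers = []
        for v in grid:
            world = replace(
                params,
                transitions=params.transitions.with_value(
                    "transitions.maintenance.AZA.esrd", v
                ),
            )
            icers.append(_pair_icer(world, STRATEGIES["S3"], STRATEGIES["S1"]))
        diffs = np.diff(icers)
        assert (diffs > 0).all() or (diffs < 0).all()

    def test_aza_esrd_among_top_tornado_parameters(self, params):
        """The maintenance-phase ESRD risk under AZA should rank among the
        most influential parameters for the S3-vs-S1 comparison."""
        results = one_way_dsa(params)
        top12 = [r.parameter for r in results[:12]]
        assert "transitions.maintenance.AZA.esrd" in top12

    def test_tornado_table_truncation(self, params):
        results = one_way_dsa(params)
        assert len(tornado_table(results, top=12)) == 12
        assert len(tornado_table(results, top=None)) == len(results)
        spreads = tornado_table(results, top=None)["spread"].values
        assert (np.diff(spreads) <= 1e-9).all()  # sorted descending


class TestDistributions:
    def test_point_mass_for_degenerate_bounds(self, params):
        specs = build_distributions(params)
        rng = np.random.default_rng(0)
        spec = DistributionSpec("point", ("x",), {"value": 3.0})
        assert spec.sample(rng) == {"x": 3.0}
        # every spec samples without error and respects its domain
        for s in specs:
            vals = s.sample(rng)
            for name, v in vals.items():
                if name.startswith("transitions."):
                    assert 0.0 <= v <= 1.0
                if name.startswith("utilities."):
                    assert 0.0 <= v <= 1.0
                if name.startswith("costs."):
                    assert v >= 0.0

    def test_dirichlet_rows_stay_on_simplex(self, params):
        specs = {s.names: s for s in build_distributions(params) if s.family == "dirichlet"}
        key = tuple(
            f"transitions.maintenance.AZA.{k}" for k in ("relapse", "esrd", "death")
        )
        rng = np.random.default_rng(123)
        for _ in range(200):
            vals = specs[key].sample(rng)
            assert sum(vals.values()) <= 1.0 + 1e-12

    def test_gamma_moment_recovery(self):
        spec = DistributionSpec(
            "gamma", ("costs.x",),
            {"shape": (100 / ((150 - 50) / 3.92)) ** 2,
             "scale": ((150 - 50) / 3.92) ** 2 / 100},
        )
        rng = np.random.default_rng(99)
        draws = np.array([spec.sample(rng)["costs.x"] for _ in range(10_000)])
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 100.0) < 2 * se + 0.5

    def test_discount_two_point(self, params):
        spec = next(
            s for s in build_distributions(params)
            if s.names == ("economics.discount_per_cycle",)
        )
        rng = np.random.default_rng(5)
        vals = {spec.sample(rng)["economics.discount_per_cycle"] for _ in range(50)}
        assert vals == {params.settings.discount_low, params.settings.discount_high}


class TestPSA:
    def test_degenerate_distributions_reproduce_deterministic_run(self, params):
        refs = enumerate_parameters(params)
        dists = [
            DistributionSpec("point", (r.name,), {"value": r.base}) for r in refs
        ]
        samples = run_psa(params, n_draws=1, seed=0, distributions=dists)
        model = build_model(STRATEGIES["S3"], params)
        trace = simulate(model, params.settings)
        det = accumulate(trace, model, params.settings)
        psa_res = samples[0].results["S3"]
        assert psa_res.total_cost == pytest.approx(det.total_cost, rel=1e-12)
        assert psa_res.total_qaly == pytest.approx(det.total_qaly, rel=1e-12)

    def test_same_seed_identical_samples(self, params):
        a = run_psa(params, n_draws=3, seed=11)
        b = run_psa(params, n_draws=3, seed=11)
        for sa, sb in zip(a, b):
            assert sa.values == sb.values
            for label in sa.results:
                assert sa.results[label].total_cost == sb.results[label].total_cost

    def test_psa_mean_near_base_case(self, params):
        """Sampled-world QALYs are approximately unbiased for the base case."""
        samples = run_psa(params, n_draws=60, seed=2)
        model = build_model(STRATEGIES["S6"], params)
        det = accumulate(simulate(model, params.settings), model, params.settings)
        qalys = np.array([s.results["S6"].total_qaly for s in samples])
        se = qalys.std(ddof=1) / np.sqrt(qalys.size)
        assert abs(qalys.mean() - det.total_qaly) < 4 * se + 0.05


class TestCEAC:
    def test_acceptabilities_sum_to_one(self, params):
        samples = run_psa(params, n_draws=25, seed=3)
        points = ceac(samples, [0.0, 10_319.0, 30_957.0, 50_000.0])
        for p in points:
            assert sum(p.acceptability.values()) == pytest.approx(1.0)
            assert all(v >= 0 for v in p.acceptability.values())

    def test_single_strategy_always_accepted(self, params):
        samples = run_psa(
            params, n_draws=5, seed=4, strategies=[STRATEGIES["S1"]]
        )
        points = ceac(samples, [0.0, 20_000.0])
        for p in points:
            assert p.acceptability["S1"] == pytest.approx(1.0)

    def test_wtp_zero_prefers_cheapest(self, params):
        samples = run_psa(params, n_draws=20, seed=6)
        (point,) = ceac(samples, [0.0])
        for s in samples:
            cheapest = min(s.results, key=lambda l: s.results[l].total_cost)
            assert s.results[cheapest].total_cost <= min(
                r.total_cost for r in s.results.values()
            )
        winner = max(point.acceptability, key=point.acceptability.get)
        count = sum(
            1 for s in samples
            if min(s.results, key=lambda l: s.results[l].total_cost) == winner
        )
        assert point.acceptability[winner] == pytest.approx(count / len(samples), abs=0.05)

    def test_ceac_matches_pairwise_nmb_ordering_two_strategies(self, params):
        samples = run_psa(
            params, n_draws=30, seed=8,
            strategies=[STRATEGIES["S1"], STRATEGIES["S3"]],
        )
        wtp = 10_319.0
        (point,) = ceac(samples, [wtp])
        wins = sum(
            1
            for s in samples
            if net_monetary_benefit(s.results["S3"], wtp)
            > net_monetary_benefit(s.results["S1"], wtp)
        )
        assert point.acceptability["S3"] == pytest.approx(wins / len(samples))

    def test_empty_grid_rejected(self, params):
        samples = run_psa(params, n_draws=2, seed=9)
        with pytest.raises(ParameterError):
            ceac(samples, [])

    def test_default_grid_contains_gdp_thresholds(self, params):
        grid = default_wtp_grid(params.settings)
        assert {params.settings.wtp_1x, params.settings.wtp_3x} <= set(grid)
        assert min(grid) == 0.0
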