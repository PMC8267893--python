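"""Monte Carlo probabilistic sensitivity analysis and its quadrature oracle."""

import numpy as np
import pytest

from qtcda import (
    EffectSizeRecord,
    EffectTable,
    EvaluationGrid,
    PsaConfig,
    evaluate_grid,
    quadrature_oracle,
    run_psa,
    sample_effects,
)
from qtcda.psa import PsaError


def degenerate_table():
    """Reference point estimates with zero-width intervals."""
    from qtcda import reference_table

    recs = tuple(
        EffectSizeRecord(r.name, r.p, r.p, r.p, r.dqtc, r.dqtc, r.dqtc)
        for r in reference_table()
    )
    return EffectTable(records=recs, p0=0.5)


class TestSampleEffects:
    def test_degenerate_records_reproduce_point_values(self):
        t = degenerate_table()
        p, q = sample_effects(t, PsaConfig(n_draws=50, seed=1), np.random.default_rng(1))
        for i, rec in enumerate(t):
            assert np.all(p[i] == rec.p)
            assert np.all(q[i] == rec.dqtc)

    def test_sampled_probability_quantiles_recover_plausible_range(self, table):
        # by construction of the log-OR normal, the 2.5/97.5 percentiles of the
        # sampled probability must land on the published plausible-range bounds
        cfg = PsaConfig(n_draws=100_000, seed=7)
        p, _ = sample_effects(table, cfg, np.random.default_rng(7))
        i = table.names.index("Amisulpride")
        lo, hi = np.percentile(p[i], [2.5, 97.5])
        assert lo == pytest.approx(0.153, abs=0.01)
        assert hi == pytest.approx(0.989, abs=0.01)

    def test_sampled_qtc_mean_recovers_point(self, table):
        cfg = PsaConfig(n_draws=100_000, seed=7)
        _, q = sample_effects(table, cfg, np.random.default_rng(7))
        i = table.names.index("Haloperidol")
        sd = (3.64 - (-0.23)) / (2 * 1.959964)
        assert q[i].mean() == pytest.approx(1.69, abs=3 * sd / np.sqrt(cfg.n_draws))

    def test_probabilities_always_inside_unit_interval(self, table):
        p, _ = sample_effects(table, PsaConfig(n_draws=20_000, seed=3), np.random.default_rng(3))
        assert np.all((p > 0) & (p < 1))

    def test_truncated_normal_scale_stays_in_bounds(self, table):
        cfg = PsaConfig(n_draws=5_000, seed=3, probability_scale="truncated_normal_p")
        p, _ = sample_effects(table, cfg, np.random.default_rng(3))
        assert np.all((p > 0) & (p < 1))

    def test_invalid_config_rejected(self):
        with pytest.raises(PsaError):
            PsaConfig(n_draws=0)
        with pytest.raises(PsaError):
            PsaConfig(probability_scale="beta")


class TestRunPsa:
    def test_seed_reproducibility_bitwise(self, table, grid, pair):
        cfg = PsaConfig(n_draws=2_000, seed=42)
        r1 = run_psa(table, grid, pair, cfg)
        r2 = run_psa(table, grid, pair, cfg)
        assert r1.summary.equals(r2.summary)

    def test_p_highest_sums_to_100_at_each_baseline(self, table, grid, pair):
        r = run_psa(table, grid, pair, PsaConfig(n_draws=5_000, seed=11))
        sums = r.summary.groupby("baseline")["p_highest"].sum()
        assert np.allclose(sums, 100.0, atol=0.5)

    def test_degenerate_cis_collapse_to_deterministic_analysis(self, grid, pair):
        t = degenerate_table()
        r = run_psa(t, grid, pair, PsaConfig(n_draws=500, seed=5))
        m = evaluate_grid(t, grid, pair)
        for name in ("Placebo", *t.names):
            for b in grid.baselines:
                cell = r.cell(name, b)
                # mean of identical draws, up to pairwise-summation rounding
                assert cell["mean"] == pytest.approx(m.loc[name, b], rel=1e-12)
                assert cell["sd"] == pytest.approx(0.0, abs=1e-10)
        # one option takes every draw at each baseline
        for b in grid.baselines:
            shares = r.summary.loc[r.summary["baseline"] == b, "p_highest"]
            assert sorted(shares)[-1] == 100.0

    def test_sd_shrinks_as_intervals_narrow(self, table, grid, pair):
        from qtcda import reference_table

        def shrunk(factor):
            recs = []
            for r in reference_table():
                import math

                logit = lambda x: math.log(x / (1 - x))  # noqa: E731
                inv = lambda y: 1 / (1 + math.exp(-y))  # noqa: E731
                m = logit(r.p)
                recs.append(
                    EffectSizeRecord(
                        r.name,
                        r.p,
                        inv(m + factor * (logit(r.p_lo) - m)),
                        inv(m + factor * (logit(r.p_hi) - m)),
                        r.dqtc,
                        r.dqtc + factor * (r.dqtc_lo - r.dqtc),
                        r.dqtc + factor * (r.dqtc_hi - r.dqtc),
                    )
                )
            return EffectTable(records=tuple(recs), p0=0.5)

        cfg = PsaConfig(n_draws=4_000, seed=9)
        wide = run_psa(shrunk(1.0), grid, pair, cfg).cell("Quetiapine", 480.0)["sd"]
        narrow = run_psa(shrunk(0.25), grid, pair, cfg).cell("Quetiapine", 480.0)["sd"]
        assert narrow < 0.5 * wide

    def test_haloperidol_beats_placebo_in_at_least_95pct(self, table, grid, pair):
        r = run_psa(table, grid, pair, PsaConfig(n_draws=10_000, seed=20210625))
        for b in grid.baselines:
            assert r.cell("Haloperidol", b)["p_beats_placebo"] >= 95.0

    def test_top_psa_option_per_baseline_matches_published_pattern(self, table, grid, pair):
        r = run_psa(table, grid, pair, PsaConfig(n_draws=10_000, seed=20210625))
        for b, expected in [(420.0, "Amisulpride"), (450.0, "Quetiapine"),
                            (480.0, "Quetiapine"), (510.0, "Quetiapine")]:
            sub = r.summary[r.summary["baseline"] == b]
            assert sub.loc[sub["p_highest"].idxmax(), "name"] == expected

    def test_mc_se_consistency(self, table, grid, pair):
        r = run_psa(table, grid, pair, PsaConfig(n_draws=2_500, seed=2))
        drug = r.summary[r.summary["name"] != "Placebo"]
        assert np.allclose(drug["mc_se"], drug["sd"] / np.sqrt(2_500))

    def test_table3_style_contains_fixed_placebo_row(self, table, grid, pair):
        r = run_psa(table, grid, pair, PsaConfig(n_draws=200, seed=1))
        styled = r.table3_style()
        assert ("Placebo", "Utility (fixed)") in styled.index
        assert styled.shape[1] == 4


class TestQuadratureOracle:
    def test_degenerate_distributions_recover_point_utility(self, pair):
        rec = EffectSizeRecord("x", 0.7, 0.7, 0.7, 5.0, 5.0, 5.0)
        from qtcda import evaluate_treatment

        assert quadrature_oracle(rec, 450.0, pair) == pytest.approx(
            evaluate_treatment(rec, 450.0, pair), rel=1e-12
        )

    def test_monte_carlo_mean_matches_oracle_on_every_cell(self, table, grid, pair):
        r = run_psa(table, grid, pair, PsaConfig(n_draws=10_000, seed=20210625))
        for rec in table:
            for b in grid.baselines:
                cell = r.cell(rec.name, b)
                oracle = quadrature_oracle(rec, b, pair)
                assert abs(cell["mean"] - oracle) <= 3 * cell["mc_se"], (rec.name, b)

    def test_jensen_gap_sign_in_the_concave_region(self, pair):
        # QTc uncertainty wholly below the inflection point sits in the concave
        # region of the sigmoid, so the mean utility must not exceed the
        # point-estimate utility (Jensen); probability held degenerate
        rec = EffectSizeRecord("x", 0.7, 0.7, 0.7, 0.0, -20.0, 20.0)
        from qtcda import evaluate_treatment

        point = evaluate_treatment(rec, 430.0, pair)
        assert quadrature_oracle(rec, 430.0, pair) <= point
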