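import numpy as np
import pandas as pd
import pytest

from cacaopheno import (
    SimConfig,
    generate_trial,
    genetic_parameters,
    pod_index,
    repeatability,
    seed_index,
    variance_components,
)
from cacaopheno.tables import TrialTable

# Published genetic-parameter estimates for a 113-accession cacao collection:
# descriptor, mean, GV, PV, GCV%, PCV%, H2%, GA, GAM% — used here as a
# self-consistency oracle for the derived-parameter formulas.
REFERENCE_ROWS = [
    ("LL", 27.90, 0.60, 1.51, 2.78, 4.40, 39.91, 1.01, 3.62),
    ("LW", 9.72, 0.17, 0.40, 4.22, 6.52, 41.83, 0.55, 5.62),
    ("PtL", 1.84, 0.01, 0.07, 6.35, 14.10, 20.28, 0.11, 5.89),
    ("PdL", 1.63, 0.05, 0.09, 14.26, 17.95, 63.11, 0.38, 23.34),
    ("SpL", 7.92, 0.96, 1.27, 12.36, 14.21, 75.59, 1.75, 22.13),
    ("SW", 2.63, 0.22, 0.28, 17.71, 20.27, 76.30, 0.84, 31.86),
    ("PL", 3.90, 0.16, 0.23, 10.40, 12.36, 70.82, 0.70, 18.03),
    ("PW", 2.11, 0.04, 0.08, 9.08, 13.21, 47.26, 0.27, 12.86),
    ("LgW", 2.71, 0.10, 0.19, 11.43, 16.16, 50.05, 0.45, 16.66),
    ("FL", 3.99, 1.67, 2.06, 32.36, 35.98, 80.90, 2.39, 59.96),
    ("StL", 6.76, 0.36, 0.50, 8.84, 10.46, 71.38, 1.04, 15.38),
    ("SL", 3.35, 0.01, 0.65, 2.99, 24.02, 1.55, 0.03, 0.77),
    ("OL", 1.71, 0.04, 0.09, 11.89, 17.43, 46.50, 0.29, 16.70),
    ("OW", 1.23, 0.03, 0.05, 14.31, 17.64, 65.76, 0.29, 23.90),
    ("SH", 0.36, 0.01, 0.01, 27.90, 27.90, 100.00, 0.21, 57.48),
    ("FM", 767.30, 53286.70, 68984.54, 30.08, 34.23, 77.24, 417.94, 54.47),
    ("FrL", 19.54, 7.29, 10.56, 13.81, 16.62, 69.04, 4.62, 23.65),
    ("FW", 9.85, 0.67, 1.05, 8.32, 10.38, 64.19, 1.35, 13.73),
    ("PrT", 2.06, 0.13, 0.19, 17.58, 20.97, 70.27, 0.63, 30.36),
    ("GD", 1.34, 0.08, 0.10, 21.17, 23.31, 82.47, 0.53, 39.61),
    ("PM", 545.16, 34718.83, 47675.19, 34.18, 40.05, 72.82, 327.56, 60.08),
    ("NL", 4.89, 0.02, 0.02, 2.57, 2.57, 100.00, 0.26, 5.30),
    ("TSS", 17.35, 1.51, 1.51, 7.09, 7.09, 100.00, 2.53, 14.60),
    ("NSL", 7.86, 0.67, 2.60, 10.43, 20.52, 25.81, 0.86, 10.91),
    ("FSMF", 147.29, 985.50, 1809.02, 21.31, 28.88, 54.48, 47.73, 32.41),
    ("NSF", 40.39, 24.52, 57.81, 12.26, 18.82, 42.42, 6.64, 16.45),
    ("SI", 1.28, 0.03, 0.11, 13.86, 25.51, 29.55, 0.20, 15.52),
    ("PI", 20.57, 1.60, 64.09, 6.15, 38.93, 2.50, 0.41, 2.00),
    ("NIS", 36.36, 18.69, 61.61, 11.89, 21.59, 30.33, 4.90, 13.49),
    ("NES", 4.03, 1.32, 8.40, 28.48, 71.86, 15.71, 0.94, 23.26),
    ("SeL", 26.12, 2.35, 5.14, 5.87, 8.68, 45.78, 2.14, 8.18),
    ("SD", 13.88, 0.86, 2.16, 6.67, 10.59, 39.74, 1.20, 8.67),
    ("ST", 9.09, 0.28, 1.82, 5.79, 14.83, 15.25, 0.42, 4.66),
]


class TestIndices:
    def test_seed_index_is_mean_single_seed_mass(self):
        assert seed_index([1.2, 1.3, 1.4]) == pytest.approx(1.3)
        assert seed_index([2.0]) == 2.0
        # 40 seeds totaling 51.2 g
        assert seed_index(np.full(40, 51.2 / 40)) == pytest.approx(1.28)

    def test_seed_index_input_validation(self):
        with pytest.raises(ValueError):
            seed_index([])
        with pytest.raises(ValueError):
            seed_index([1.0, -0.5])

    def test_pod_index_values(self):
        assert pod_index(1000, 1.0) == pytest.approx(1.0)
        assert pod_index(40, 1.25) == pytest.approx(20.0)

    def test_pod_index_monotone_decreasing(self):
        base = pod_index(40, 1.25)
        assert pod_index(41, 1.25) < base
        assert pod_index(40, 1.30) < base
        with pytest.raises(ValueError):
            pod_index(0, 1.0)


def _balanced_trial(cells):
    """cells: genotype -> list of replicate values (one per replication)."""
    rows = []
    for g, vals in cells.items():
        for j, v in enumerate(vals):
            rows.append((g, f"R{j}", 2023, "FM", float(v)))
    return TrialTable(
        pd.DataFrame(
            rows, columns=["accession", "replicate", "season", "descriptor", "value"]
        )
    )


class TestVarianceComponents:
    def test_matches_two_way_anova_oracle(self, rng):
        # independent oracle: statsmodels OLS two-way ANOVA on the same data
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        vals = rng.normal(size=(3, 4)) + np.array([[0], [2], [5]])
        trial = _balanced_trial({f"G{i}": vals[i] for i in range(3)})
        vc = variance_components(trial, "FM")

        df = trial.data.copy()
        df["value"] = df["value"].astype(float)
        fit = smf.ols("value ~ C(replicate) + C(accession)", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=1)
        msg = tab.loc["C(accession)", "sum_sq"] / tab.loc["C(accession)", "df"]
        mse = tab.loc["Residual", "sum_sq"] / tab.loc["Residual", "df"]
        assert vc.MSG == pytest.approx(msg, rel=1e-9)
        assert vc.MSE == pytest.approx(mse, rel=1e-9)
        assert vc.r_eff == 4.0
        # expected-mean-squares identity
        assert vc.GV == pytest.approx(max((msg - mse) / 4.0, 0.0), rel=1e-9)

    def test_unbalanced_matches_sequential_anova_oracle(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rows = []
        for i, n in enumerate([4, 3, 5, 2]):
            for j in range(n):
                rows.append((f"G{i}", f"R{j}", 2023, "FM",
                             float(rng.normal(i * 2, 1))))
        trial = TrialTable(
            pd.DataFrame(
                rows,
                columns=["accession", "replicate", "season", "descriptor", "value"],
            )
        )
        vc = variance_components(trial, "FM")
        df = trial.data.copy()
        df["value"] = df["value"].astype(float)
        fit = smf.ols("value ~ C(replicate) + C(accession)", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=1)
        msg = tab.loc["C(accession)", "sum_sq"] / tab.loc["C(accession)", "df"]
        mse = tab.loc["Residual", "sum_sq"] / tab.loc["Residual", "df"]
        assert vc.MSG == pytest.approx(msg, rel=1e-9)
        assert vc.MSE == pytest.approx(mse, rel=1e-9)

    def test_constant_data_gives_zero_variance(self):
        trial = _balanced_trial({"G1": [5, 5, 5], "G2": [5, 5, 5]})
        vc = variance_components(trial, "FM")
        assert vc.MSG == 0.0 and vc.MSE == 0.0 and vc.GV == 0.0

    def test_single_replication_rejected(self):
        trial = _balanced_trial({"G1": [1.0], "G2": [2.0]})
        with pytest.raises(ValueError, match="residual"):
            variance_components(trial, "FM")

    def test_unbiased_on_simulation(self):
        # mean GV estimate over seeds within 10% of planted GV = 4
        ests = []
        for seed in range(60):
            cfg = SimConfig(
                n_accessions=113, n_reps=6, K_true=8, seed=seed,
                traits={"FM": (50.0, 4.0, 1.0)}, qual_traits=[],
            )
            trial, _ = generate_trial(cfg)
            ests.append(variance_components(trial, "FM").GV)
        assert np.mean(ests) == pytest.approx(4.0, rel=0.10)


class TestGeneticParameters:
    @pytest.mark.parametrize(
        "acr,mean,gv,pv,gcv,pcv,h2,ga,gam", REFERENCE_ROWS,
        ids=[r[0] for r in REFERENCE_ROWS],
    )
    def test_reference_rows_self_consistent(
        self, acr, mean, gv, pv, gcv, pcv, h2, ga, gam
    ):
        # inputs are printed at 2 decimals, so the recomputed parameter is
        # bracketed by evaluating the (monotone) formulas at the rounding
        # extremes of (mean, GV, PV); the printed value must fall in that
        # bracket widened by 0.05 (0.5 for GA, which is in trait units)
        h = 0.005

        def bracket(fn):
            vals = [
                fn(gv + s1 * h, pv + s2 * h, mean + s3 * h)
                for s1 in (-1, 1) for s2 in (-1, 1) for s3 in (-1, 1)
            ]
            return min(vals), max(vals)

        def gp(g, p, m):
            return genetic_parameters(g, max(p - g, 0.0), m, k=2.06)

        checks = [
            (gcv, lambda g, p, m: gp(g, p, m).GCV, 0.05),
            (pcv, lambda g, p, m: gp(g, p, m).PCV, 0.05),
            (h2, lambda g, p, m: gp(g, p, m).H2, 0.05),
            (ga, lambda g, p, m: gp(g, p, m).GA, 0.5),
            (gam, lambda g, p, m: gp(g, p, m).GAM, 0.05),
        ]
        for printed, fn, tol in checks:
            lo, hi = bracket(fn)
            assert lo - tol <= printed <= hi + tol, (acr, printed, lo, hi)

    def test_no_genetic_variance_degenerate_case(self):
        gp = genetic_parameters(0.0, 1.0, 10.0)
        assert gp.GCV == 0.0 and gp.H2 == 0.0 and gp.GA == 0.0 and gp.GAM == 0.0

    def test_gcv_never_exceeds_pcv(self, rng):
        for _ in range(50):
            gv, ev = rng.uniform(0, 10, 2)
            gp = genetic_parameters(gv, ev, rng.uniform(1, 100))
            assert gp.GCV <= gp.PCV + 1e-12
        # equality iff EV = 0
        gp = genetic_parameters(5.0, 0.0, 10.0)
        assert gp.GCV == pytest.approx(gp.PCV)
        assert gp.H2 == pytest.approx(100.0)

    def test_ga_monotone_in_selection_differential(self):
        lo = genetic_parameters(4.0, 1.0, 10.0, k=1.40)
        hi = genetic_parameters(4.0, 1.0, 10.0, k=2.06)
        assert hi.GA > lo.GA and hi.GAM > lo.GAM

    def test_band_labels(self):
        gp = genetic_parameters(53286.70, 68984.54 - 53286.70, 767.30)
        assert gp.GCV_band == "high"      # 30.08
        assert gp.H2_band == "high"       # 77.24
        assert gp.GAM_band == "high"      # 54.47
        low = genetic_parameters(0.60, 1.51 - 0.60, 27.90)
        assert low.GCV_band == "low" and low.H2_band == "moderate"

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            genetic_parameters(1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            genetic_parameters(0.0, 0.0, 5.0)


def _two_season_trial(means_by_acc_season, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for acc, season_means in means_by_acc_season.items():
        for season, m in season_means.items():
            for j in range(2):
                rows.append(
                    (acc, f"R{j}", season, "SI", float(m + noise * rng.normal()))
                )
    return TrialTable(
        pd.DataFrame(
            rows, columns=["accession", "replicate", "season", "descriptor", "value"]
        )
    )


class TestRepeatability:
    def test_identical_season_means_give_unity(self):
        trial = _two_season_trial(
            {f"A{i}": {2023: i, 2024: i} for i in range(1, 6)}
        )
        est = repeatability(trial, "SI")
        assert est.r_hat == pytest.approx(1.0)
        assert est.label == "moderate-to-high"

    def test_no_accession_effect_gives_near_zero(self):
        rng = np.random.default_rng(42)
        trial = _two_season_trial(
            {f"A{i}": {2023: rng.normal(), 2024: rng.normal()}
             for i in range(200)}
        )
        est = repeatability(trial, "SI")
        assert abs(est.r_hat) < 0.15
        assert est.label == "low"
        assert est.r_reported >= 0.0

    def test_planted_icc_recovered(self):
        # accession variance 0.6, season-mean noise 0.4 -> ICC = 0.6
        ests = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            acc_eff = rng.normal(0, np.sqrt(0.6), 113)
            trial = _two_season_trial(
                {
                    f"A{i:03d}": {
                        2023: acc_eff[i] + rng.normal(0, np.sqrt(0.4)),
                        2024: acc_eff[i] + rng.normal(0, np.sqrt(0.4)),
                    }
                    for i in range(113)
                }
            )
            ests.append(repeatability(trial, "SI").r_hat)
        assert np.mean(ests) == pytest.approx(0.6, abs=0.08)

    def test_single_season_rejected(self):
        trial = _two_season_trial({f"A{i}": {2023: float(i)} for i in range(5)})
        with pytest.raises(ValueError):
            repeatability(trial, "SI")
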