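"""Fitting engines: backward elimination, FP search, volume model, staging."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stagedefw import (
    GeneratorConfig,
    Stage,
    default_registry,
    fit_fpr,
    fit_mlr,
    fit_staged,
    fit_vm,
    generate,
)
from stagedefw.fitting import (
    FP_POWERS,
    Composite,
    FittingError,
    FractionalPolynomialModel,
    InteractionMLR,
    SampleSizeError,
    VolumeModel,
    backward_eliminate,
    fp_basis,
)
from stagedefw.formulas import Factor


def _biometry_frame(n: int, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "ga_weeks": rng.uniform(28, 43, n),
            "bpd_cm": rng.uniform(7.0, 9.8, n),
            "hc_cm": rng.uniform(25.5, 35.0, n),
            "ac_cm": rng.uniform(23.0, 35.5, n),
            "fl_cm": rng.uniform(5.0, 7.8, n),
        }
    )


def exhaustive_admissible_subset(y, columns, alpha):
    """Independent best-subset oracle: smallest-RSS subset whose every
    term is significant at ``alpha`` (raw numpy/scipy, no statsmodels)."""
    y = np.asarray(y, float)
    names = list(columns)
    n = y.size
    best = None  # (rss, subset)
    for r in range(len(names) + 1):
        for subset in itertools.combinations(names, r):
            X = np.column_stack(
                [np.ones(n)] + [np.asarray(columns[c], float) for c in subset]
            )
            p = X.shape[1]
            if n <= p:
                continue
            xtx_inv = np.linalg.pinv(X.T @ X)
            beta = xtx_inv @ X.T @ y
            resid = y - X @ beta
            rss = float(resid @ resid)
            df = n - p
            sigma2 = rss / df
            se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 1e-300))
            tvals = beta / se
            pvals = 2 * stats.t.sf(np.abs(tvals), df)
            if np.all(pvals[1:] < alpha):
                if best is None or rss < best[0]:
                    best = (rss, frozenset(subset))
    return best[1]


class TestBackwardElimination:
    def test_noiseless_single_interaction_recovered(self):
        """log10 W generated from one HC*AC term: that term survives,
        everything else is eliminated, coefficient recovered ~exactly."""
        df = _biometry_frame(400, seed=2)
        rng = np.random.default_rng(5)
        log10w = 2.7 + 0.002 * df["hc_cm"] * df["ac_cm"]
        df["birth_weight_g"] = 10 ** (log10w + rng.normal(0, 1e-6, len(df)))
        res = fit_mlr(df, alpha=0.05)
        retained = [n for n in res.params.index if n != "intercept"]
        assert retained == ["HC*AC"]
        assert res.params["HC*AC"] == pytest.approx(0.002, abs=1e-8)
        assert res.params["intercept"] == pytest.approx(2.7, abs=1e-5)

    def test_pure_noise_gives_intercept_only(self):
        df = _biometry_frame(400, seed=4)
        rng = np.random.default_rng(4)
        df["birth_weight_g"] = 10 ** rng.normal(3.5, 0.05, len(df))
        res = fit_mlr(df, alpha=0.05)
        assert list(res.params.index) == ["intercept"]
        assert len(res.trace) == 10  # all mains + interactions removed

    def test_alpha_one_eliminates_nothing(self):
        df = _biometry_frame(400, seed=5)
        df["birth_weight_g"] = 3000.0 + 50 * df["ac_cm"]
        res = fit_mlr(df, alpha=1.0)
        assert len(res.params) == 11  # intercept + 4 mains + 6 interactions

    def test_sample_size_guard(self):
        df = _biometry_frame(50, seed=6)
        df["birth_weight_g"] = 3000.0
        with pytest.raises(SampleSizeError):
            InteractionMLR(df)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_subset_oracle(self, seed):
        """Greedy elimination lands on the oracle's best admissible subset."""
        rng = np.random.default_rng(seed)
        n, k = 300, 7
        X, _ = np.linalg.qr(rng.standard_normal((n, k)))
        X *= np.sqrt(n)
        truth = rng.uniform(size=k) < 0.5
        beta = np.where(truth, rng.choice([-1, 1], k) * rng.uniform(0.5, 1.0, k), 0.0)
        y = X @ beta + rng.standard_normal(n)
        cols = {f"x{i}": X[:, i] for i in range(k)}
        retained, _, _ = backward_eliminate(y, cols, alpha=0.05)
        assert frozenset(retained) == exhaustive_admissible_subset(y, cols, 0.05)


class TestFractionalPolynomial:
    def test_candidate_counts(self):
        cands = FractionalPolynomialModel.candidate_power_sets()
        fp1 = [c for c in cands if len(c) == 1]
        fp2 = [c for c in cands if len(c) == 2]
        assert len(fp1) == 8 and len(fp2) == 36 and len(cands) == 44

    def test_repeated_power_basis(self):
        x = np.array([0.5, 1.0, 2.0, 3.0])
        b = fp_basis(x, (-2.0, -2.0))
        assert np.allclose(b[0], x ** -2)
        assert np.allclose(b[1], x ** -2 * np.log(x))
        b0 = fp_basis(x, (0.0, 0.0))
        assert np.allclose(b0[0], np.log(x))
        assert np.allclose(b0[1], np.log(x) ** 2)

    def test_fp1_identifies_square_law(self):
        """y = x^2 (+ tiny noise) over x in [1,3] selects power 2."""
        rng = np.random.default_rng(8)
        n = 400
        x = rng.uniform(1.0, 3.0, n)
        df = pd.DataFrame(
            {
                "ga_weeks": np.full(n, 38.0),
                "bpd_cm": np.full(n, 9.0),
                "hc_cm": np.full(n, 33.0),
                "ac_cm": 10.0 * x,  # composite AC/10 equals x
                "fl_cm": np.full(n, 7.0),
                "birth_weight_g": 10 ** (0.3 * x ** 2 + rng.normal(0, 1e-4, n)),
            }
        )
        model = FractionalPolynomialModel(df, degree=1)
        powers, dev = model.search_composite(Composite(("AC",), 10.0))
        assert powers == (2.0,)
        assert dev[powers] <= min(dev.values()) + 1e-9

    def test_selected_deviance_is_minimal(self, midsize_cohort):
        sl = midsize_cohort.stage_slice(Stage.S37_39).head(1200)
        model = FractionalPolynomialModel(sl)
        powers, dev = model.search_composite(Composite(("AC", "FL"), 100.0))
        assert len(dev) == 44
        assert dev[powers] == min(dev.values())

    def test_non_positive_composite_rejected(self):
        df = _biometry_frame(100, seed=9)
        df.loc[0, "ac_cm"] = 31.0
        df["birth_weight_g"] = 3000.0
        bad = df.copy()
        bad["ac_cm"] = -bad["ac_cm"]
        with pytest.raises(FittingError):
            FractionalPolynomialModel(bad).search_composite(
                Composite(("AC",), 10.0)
            )

    def test_fitted_formula_reproduces_design_prediction(self, midsize_cohort):
        """The declarative FormulaSpec round-trips the fitted linear model."""
        sl = midsize_cohort.stage_slice(Stage.S40_42).head(1000)
        res = fit_fpr(sl)
        efw = res.predict(sl)
        assert np.all(np.isfinite(efw)) and np.all(efw > 200)


class TestVolumeModel:
    def test_noiseless_recovery(self):
        df = _biometry_frame(300, seed=10)
        df["birth_weight_g"] = (
            1.2 * df["bpd_cm"] ** 3 + 0.25 * df["fl_cm"] * df["ac_cm"] ** 2
        )
        res = fit_vm(df)
        assert res.extra["selected_head"] == "BPD^3"
        assert res.params["BPD^3"] == pytest.approx(1.2, abs=1e-8)
        assert res.params["FL*AC^2"] == pytest.approx(0.25, abs=1e-8)

    def test_selection_is_exhaustive_min_rss(self):
        df = _biometry_frame(500, seed=11)
        rng = np.random.default_rng(11)
        df["birth_weight_g"] = (
            0.046 * df["bpd_cm"] * df["hc_cm"] ** 2
            + 0.333 * df["fl_cm"] * df["ac_cm"] ** 2
        ) * np.exp(rng.normal(0, 0.07, len(df)))
        res = fit_vm(df)
        sel = res.extra["selected_head"]
        attempts = res.extra["head_selection"]
        admissible = {k: v["rss"] for k, v in attempts.items() if v["admissible"]}
        assert sel == min(admissible, key=admissible.get)
        assert len(attempts) == 4

    def test_residuals_orthogonal_to_basis(self):
        df = _biometry_frame(400, seed=12)
        rng = np.random.default_rng(12)
        df["birth_weight_g"] = (
            0.09 * df["bpd_cm"] * df["hc_cm"] ** 2
            + 0.29 * df["fl_cm"] * df["ac_cm"] ** 2
        ) * np.exp(rng.normal(0, 0.05, len(df)))
        res = fit_vm(df)
        head_name = res.extra["selected_head"]
        b = {
            "BPD": df["bpd_cm"].to_numpy(), "HC": df["hc_cm"].to_numpy(),
            "AC": df["ac_cm"].to_numpy(), "FL": df["fl_cm"].to_numpy(),
        }
        cols = {
            "HC^3": b["HC"] ** 3, "BPD^3": b["BPD"] ** 3,
            "BPD*HC^2": b["BPD"] * b["HC"] ** 2,
            "BPD^2*HC": b["BPD"] ** 2 * b["HC"],
        }
        head = cols[head_name]
        trunk = b["FL"] * b["AC"] ** 2
        resid = df["birth_weight_g"].to_numpy() - res.predict(df)
        for col in (head, trunk):
            rel = abs(float(resid @ col)) / (
                np.linalg.norm(resid) * np.linalg.norm(col)
            )
            assert rel < 1e-8

    def test_all_candidates_rejected_raises(self):
        rng = np.random.default_rng(13)
        n = 200
        df = pd.DataFrame(
            {
                "ga_weeks": np.full(n, 38.0),
                "bpd_cm": rng.uniform(1.8, 2.2, n),
                "hc_cm": rng.uniform(4.5, 5.5, n),
                "ac_cm": rng.uniform(30.0, 35.0, n),
                "fl_cm": rng.uniform(6.5, 7.5, n),
            }
        )
        head = df["bpd_cm"] * df["hc_cm"] ** 2
        trunk = df["fl_cm"] * df["ac_cm"] ** 2
        df["birth_weight_g"] = 0.4 * trunk - 1.0 * head  # positive by design
        assert (df["birth_weight_g"] > 0).all()
        with pytest.raises(FittingError):
            VolumeModel(
                df,
                head_candidates={"BPD*HC^2": (Factor(("BPD",)),
                                              Factor(("HC",), power=2))},
            ).fit()

    def test_relative_weighting_variant_runs(self):
        df = _biometry_frame(300, seed=14)
        rng = np.random.default_rng(14)
        df["birth_weight_g"] = (
            0.05 * df["bpd_cm"] * df["hc_cm"] ** 2
            + 0.33 * df["fl_cm"] * df["ac_cm"] ** 2
        ) * np.exp(rng.normal(0, 0.07, len(df)))
        res = VolumeModel(df).fit(weighting="relative")
        assert (res.params > 0).all()


class TestFitStaged:
    def test_single_family_everywhere(self, midsize_cohort):
        staged, results = fit_staged(midsize_cohort, families="VM")
        assert all(r.family == "VM" for r in results.values())
        assert all(spec.family == "VM" for spec in staged.models.values())

    def test_recommended_family_assignment(self, midsize_cohort):
        _, results = fit_staged(midsize_cohort, families=None)
        fams = {s: r.family for s, r in results.items()}
        assert fams[Stage.S28_30] == "VM" and fams[Stage.S34_36] == "VM"
        assert fams[Stage.S37_39] == "MLR" and fams[Stage.S40_42] == "FPR"

    def test_auto_mode_records_per_family_errors(self, midsize_cohort):
        staged, results = fit_staged(midsize_cohort, families="auto")
        for stage, res in results.items():
            errs = res.extra["family_systematic_errors_pct"]
            winner = res.extra["selected_family"]
            assert winner in errs
            assert abs(errs[winner]) == min(abs(v) for v in errs.values())

    def test_empty_stage_raises(self):
        from stagedefw.biometry import Cohort

        df = _biometry_frame(300, seed=15)
        df = df[df["ga_weeks"] >= 34].reset_index(drop=True)
        df["birth_weight_g"] = 3000.0
        with pytest.raises(FittingError, match="S28_30"):
            fit_staged(Cohort(df), families="VM")


class TestParameterRecoveryScaling:
    @pytest.mark.parametrize("n, tol", [(500, 0.12), (5000, 0.05)])
    def test_vm_bias_shrinks_with_n(self, n, tol):
        truth = default_registry()["staged_vm_34_36"]
        cfg = GeneratorConfig(
            n=n, seed=42, truth=truth, noise_cv=0.07,
            stage_weights=(0.2, 0.2, 0.2, 0.2, 0.2),
        )
        cohort, _ = generate(cfg, include_centiles=False)
        res = VolumeModel(cohort.data).fit(weighting="relative")
        assert res.extra["selected_head"] == "BPD*HC^2"
        a, b = res.params.iloc[0], res.params.iloc[1]
        assert abs(a - 0.04608) / 0.04608 < tol
        assert abs(b - 0.33326) / 0.33326 < tol
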