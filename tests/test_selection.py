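import warnings
from dataclasses import replace

import numpy as np
import pytest

from psytraj.gmm import GrowthMixtureSpec, design_matrices, fit_gmm
from psytraj.selection import (
    LadderRow,
    ModelLadderResult,
    SelectionRules,
    blrt_pvalue,
    bootstrap_lrt,
    default_grid,
    label_classes,
    lmr_test,
    run_model_ladder,
    select_final_model,
)


def _two_class_data(n=90, T=5, seed=7, gap=7.0):
    rng = np.random.default_rng(seed)
    X, _ = design_matrices(T, 1)
    cls = rng.random(n) < 0.55
    mu = np.where(cls[:, None], (X @ [2.0, -0.2])[None, :], (X @ [2.0 + gap, 0.3])[None, :])
    return mu + rng.normal(0, 1.0, (n, T))


_QUICK = dict(n_starts=2, short_iter=25, max_iter=80, tol=1e-4, n_final=2)


class TestLadder:
    def test_default_grid_row_count(self):
        Y = _two_class_data()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ladder = run_model_ladder(
                Y, base_spec=GrowthMixtureSpec(**_QUICK)
            )
        assert len(ladder.rows) == 24  # 2 degrees x 2 RE x 6 class counts

    def test_k1_rows_have_missing_entropy(self):
        Y = _two_class_data()
        grid = default_grid(class_range=(1,))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ladder = run_model_ladder(Y, grid=grid, base_spec=GrowthMixtureSpec(**_QUICK))
        assert len(ladder.rows) == 4
        assert all(np.isnan(r.entropy) for r in ladder.rows if r.converged)

    def test_frame_columns(self):
        Y = _two_class_data()
        grid = default_grid(degrees=(1,), random_effects=("none",), class_range=(1, 2))
        ladder = run_model_ladder(Y, grid=grid, base_spec=GrowthMixtureSpec(**_QUICK))
        df = ladder.to_frame()
        assert {"bic", "entropy", "min_class_share", "converged"} <= set(df.columns)


class TestLMR:
    def _fits(self, Y, seed=0):
        s1 = GrowthMixtureSpec(n_classes=1, degree=1, random_effects="none", seed=seed)
        s2 = GrowthMixtureSpec(n_classes=2, degree=1, random_effects="none", n_starts=4, seed=seed)
        return fit_gmm(Y, s2), fit_gmm(Y, s1)

    def test_identical_fits_give_p_one(self):
        Y = _two_class_data()
        f2, f1 = self._fits(Y)
        f2_same = replace(f2, loglik=f1.loglik)
        stat, p = lmr_test(f2_same, f1, Y.shape[0])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_positive_statistic_when_better(self):
        Y = _two_class_data()
        f2, f1 = self._fits(Y)
        stat, p = lmr_test(f2, f1, Y.shape[0])
        assert stat > 0
        assert 0 <= p <= 1

    def test_separated_classes_detected(self):
        Y = _two_class_data(gap=8.0)
        f2, f1 = self._fits(Y)
        _, p = lmr_test(f2, f1, Y.shape[0])
        assert p < 0.01

    def test_decreasing_loglik_warns(self):
        Y = _two_class_data()
        f2, f1 = self._fits(Y)
        f_bad = replace(f2, loglik=f1.loglik - 1.0)
        with pytest.warns(UserWarning, match="decreased"):
            stat, p = lmr_test(f_bad, f1, Y.shape[0])
        assert np.isnan(p)


class TestBLRT:
    def test_pvalue_formula_all_below(self):
        assert blrt_pvalue(10.0, [1.0] * 99) == pytest.approx(0.01)

    def test_pvalue_formula_lr_zero(self):
        assert blrt_pvalue(0.0, [0.5, 0.0, 1.0]) == pytest.approx(1.0)

    def test_power_on_separated_classes(self):
        Y = _two_class_data(n=60, T=4, gap=8.0, seed=3)
        s1 = GrowthMixtureSpec(n_classes=1, degree=1, random_effects="none", seed=0)
        s2 = GrowthMixtureSpec(n_classes=2, degree=1, random_effects="none", n_starts=4, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = bootstrap_lrt(Y, s2, s1, B=50, seed=5)
        assert stat > 0
        assert p <= 0.05

    def test_reproducible_given_seed(self):
        Y = _two_class_data(n=50, T=4, seed=9)
        s1 = GrowthMixtureSpec(n_classes=1, degree=1, random_effects="none", seed=0)
        s2 = GrowthMixtureSpec(n_classes=2, degree=1, random_effects="none", n_starts=2, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = bootstrap_lrt(Y, s2, s1, B=20, seed=3)
            r2 = bootstrap_lrt(Y, s2, s1, B=20, seed=3)
        assert r1 == r2

    def test_b_validation(self):
        Y = _two_class_data(n=30, T=4)
        s1 = GrowthMixtureSpec(n_classes=1, degree=1, random_effects="none")
        s2 = GrowthMixtureSpec(n_classes=2, degree=1, random_effects="none")
        with pytest.raises(ValueError):
            bootstrap_lrt(Y, s2, s1, B=0)


def _row(k, bic, entropy=0.9, min_share=0.3, converged=True, degree=2, re="intercept_slope"):
    spec = GrowthMixtureSpec(n_classes=k, degree=degree, random_effects=re)
    return LadderRow(
        spec=spec,
        converged=converged,
        loglik=-bic / 2,
        n_params=spec.n_params(),
        bic=bic,
        entropy=entropy if k > 1 else float("nan"),
        min_class_share=min_share if k > 1 else 1.0,
    )


class TestSelectFinalModel:
    def test_single_row(self):
        ladder = ModelLadderResult(rows=[_row(1, 1000.0)])
        idx, trace = select_final_model(ladder)
        assert idx == 0

    def test_small_class_rejected_despite_better_bic(self):
        # 5-class: BIC lower by 12 but min share 3%; 4-class share 5.6%
        ladder = ModelLadderResult(
            rows=[_row(4, 1000.0, entropy=0.93, min_share=0.056),
                  _row(5, 988.0, entropy=0.94, min_share=0.03)]
        )
        idx, trace = select_final_model(ladder)
        assert ladder.rows[idx].spec.n_classes == 4
        assert any("smallest class share 0.030 < 0.05" in t for t in trace)

    def test_entropy_breaks_near_ties(self):
        ladder = ModelLadderResult(
            rows=[_row(3, 1000.0, entropy=0.80), _row(4, 1004.0, entropy=0.95)]
        )
        idx, _ = select_final_model(ladder)
        assert ladder.rows[idx].entropy == pytest.approx(0.95)

    def test_decisive_bic_gap_wins_over_entropy(self):
        ladder = ModelLadderResult(
            rows=[_row(3, 1000.0, entropy=0.80), _row(4, 1012.0, entropy=0.99)]
        )
        idx, trace = select_final_model(ladder)
        assert ladder.rows[idx].spec.n_classes == 3
        assert any("BIC disadvantage 12.0 >= 10" in t for t in trace)

    def test_fewer_classes_breaks_entropy_ties(self):
        ladder = ModelLadderResult(
            rows=[_row(4, 1000.0, entropy=0.90), _row(2, 1003.0, entropy=0.90)]
        )
        idx, _ = select_final_model(ladder)
        assert ladder.rows[idx].spec.n_classes == 2

    def test_all_rows_fail_share_rule_falls_back_with_warning(self):
        ladder = ModelLadderResult(
            rows=[_row(5, 990.0, min_share=0.01), _row(6, 995.0, min_share=0.02)]
        )
        with pytest.warns(UserWarning, match="class-share"):
            idx, trace = select_final_model(ladder)
        assert idx == 0  # best BIC

    def test_unconverged_rows_ignored(self):
        ladder = ModelLadderResult(
            rows=[_row(4, 900.0, converged=False), _row(3, 1000.0)]
        )
        idx, _ = select_final_model(ladder)
        assert idx == 1

    def test_pure_function_of_table(self):
        rows = [_row(3, 1000.0, entropy=0.85), _row(4, 1005.0, entropy=0.92)]
        l1 = ModelLadderResult(rows=list(rows))
        l2 = ModelLadderResult(rows=list(rows))
        assert select_final_model(l1) == select_final_model(l2)

    def test_empty_ladder_errors(self):
        with pytest.raises(ValueError):
            select_final_model(ModelLadderResult(rows=[_row(2, 1000.0, converged=False)]))


class TestLabelClasses:
    def _fit_with_curves(self, betas, T=10, degree=2):
        """Construct a minimal fit whose mean curves are X @ beta."""
        from psytraj.gmm import GrowthMixtureFit

        K = len(betas)
        spec = GrowthMixtureSpec(n_classes=K, degree=degree)
        return GrowthMixtureFit(
            spec=spec,
            pi=np.full(K, 1.0 / K),
            beta=np.array(betas, dtype=float),
            Sigma_b=None,
            sigma2=1.0,
            loglik=0.0,
            posteriors=np.full((K, K), 1.0 / K),
            n_params=spec.n_params(),
            converged=True,
            n_used=K,
            T=T,
        )

    def test_canonical_four_labels(self):
        # centred time: flat low, flat high, rising, falling
        fit = self._fit_with_curves(
            [[1.0, 0.0, 0.0], [11.0, 0.0, 0.0], [6.0, 1.2, 0.0], [6.0, -1.2, 0.0]]
        )
        labels = label_classes(fit)
        assert labels == {
            0: "remitting",
            1: "persistent",
            2: "late_decline",
            3: "late_improvement",
        }

    def test_k2_generic_labels(self):
        fit = self._fit_with_curves([[1.0, 0.0, 0.0], [11.0, 0.0, 0.0]][:2])
        fit.spec.n_classes = 2
        fit.pi = np.array([0.5, 0.5])
        labels = label_classes(fit)
        assert labels == {0: "class_1", 1: "class_2"}

    def test_duplicate_labels_suffixed(self):
        fit = self._fit_with_curves(
            [[1.0, 0.0, 0.0], [2.0, 0.0, 0.0], [11.0, 0.0, 0.0], [6.0, 1.2, 0.0]]
        )
        with pytest.warns(UserWarning, match="same label"):
            labels = label_classes(fit)
        assert labels[0] == "remitting_1"
        assert labels[1] == "remitting_2"

    def test_generator_default_fit_labels_match_truth(self, protocol_runs):
        run = protocol_runs[0]
        assert set(run.label_map.values()) == {
            "remitting",
            "late_decline",
            "late_improvement",
            "persistent",
        }
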