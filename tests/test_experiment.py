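"""Cross-validation harness: splits, paired testing, PCA profiling, summary."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from wsibpg.bpg import BPGModel, designate_target
from wsibpg.classify import KNNConfig
from wsibpg.experiment import (
    EvalReport,
    SplitPlan,
    make_splits,
    paired_one_tailed,
    pca_profile,
    run_setting,
    summarize_improvement,
)
from wsibpg.pooling import TrainingConfig
from wsibpg.synthetic import CohortSpec, generate_cohort


def _labels(counts: dict[str, int]) -> dict[str, str]:
    out = {}
    i = 0
    for cls, n in counts.items():
        for _ in range(n):
            out[f"s{i:04d}"] = cls
            i += 1
    return out


class TestMakeSplits:
    def test_cohort_of_633_splits_316_317(self):
        counts = {"normal": 200, "acute leukemia": 120,
                  "myelodysplastic syndrome": 100, "plasma cell neoplasm": 90,
                  "lymphoproliferative disorder": 70,
                  "myeloproliferative neoplasm": 53}
        labels = _labels(counts)
        assert len(labels) == 633
        for train, test in make_splits(labels, SplitPlan(repeats=5, base_seed=0)):
            assert len(train) == 316 and len(test) == 317

    def test_even_class_splits_in_half_every_repeat(self):
        labels = _labels({"x": 10, "y": 4})
        for train, test in make_splits(labels, SplitPlan(repeats=4)):
            assert sum(labels[s] == "x" for s in train) == 5
            assert sum(labels[s] == "x" for s in test) == 5

    def test_disjoint_exhaustive_stratified(self):
        labels = _labels({"a": 13, "b": 8, "c": 21})
        for train, test in make_splits(labels, SplitPlan(repeats=3, base_seed=2)):
            assert set(train).isdisjoint(test)
            assert set(train) | set(test) == set(labels)
            for cls, n in (("a", 13), ("b", 8), ("c", 21)):
                in_train = sum(labels[s] == cls for s in train)
                assert abs(in_train - n / 2) <= 0.5  # within one slide

    def test_deterministic_under_seeds(self):
        labels = _labels({"a": 9, "b": 6})
        plan = SplitPlan(repeats=2, seeds=(5, 6))
        assert make_splits(labels, plan) == make_splits(labels, plan)

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError, match="single"):
            make_splits(_labels({"a": 4, "b": 1}), SplitPlan(repeats=1))

    @given(
        counts=st.lists(st.integers(2, 30), min_size=2, max_size=5),
        seed=st.integers(0, 100),
    )
    def test_split_invariants_hold_generally(self, counts, seed):
        labels = _labels({f"c{i}": n for i, n in enumerate(counts)})
        (train, test), = make_splits(labels, SplitPlan(repeats=1, base_seed=seed))
        assert set(train).isdisjoint(test)
        assert set(train) | set(test) == set(labels)
        for i, n in enumerate(counts):
            in_train = sum(labels[s] == f"c{i}" for s in train)
            assert in_train == n // 2  # floor, remainder to test


class TestPairedOneTailed:
    def test_constant_positive_deltas_significant_by_convention(self):
        assert paired_one_tailed([0.02, 0.02, 0.02]) == 0.0

    def test_constant_negative_deltas_insignificant(self):
        assert paired_one_tailed([-0.02, -0.02]) == 1.0

    def test_all_zero_deltas_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            paired_one_tailed([0.0, 0.0, 0.0])

    def test_symmetric_deltas_near_half_under_permutation(self):
        p = paired_one_tailed([0.01, -0.01, 0.02, -0.02], method="permutation")
        assert p == pytest.approx(0.5, abs=0.15)

    def test_permutation_matches_exhaustive_sign_flip_oracle(self):
        deltas = np.array([0.01, 0.03, 0.02, 0.04, 0.02])
        observed = deltas.mean()
        count = 0
        for mask in range(2 ** 5):
            signs = np.array([1 if mask & (1 << i) else -1 for i in range(5)])
            if (signs * deltas).mean() >= observed - 1e-15:
                count += 1
        oracle = count / 32
        assert paired_one_tailed(deltas, method="permutation") == pytest.approx(oracle)
        # and the t variant agrees the improvement is significant
        assert paired_one_tailed(deltas, method="t") < 0.05

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_one_tailed([0.1])


class TestPCAProfile:
    def test_rank_one_data_needs_one_component(self):
        rng = np.random.default_rng(0)
        X = np.outer(rng.standard_normal(200), rng.standard_normal(10))
        q, ratio = pca_profile(X, 0.95)
        assert q == 1 and ratio == pytest.approx(0.1)

    def test_isotropic_gaussian_needs_about_95_percent_of_components(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((5000, 50))
        q, ratio = pca_profile(X, 0.95)
        assert 0.88 <= ratio <= 1.0  # near-equal eigenvalues => q ~ 0.95 d

    def test_matches_cumulative_eigenvalue_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n, d = int(rng.integers(20, 60)), int(rng.integers(3, 12))
            X = rng.standard_normal((n, d)) @ rng.standard_normal((d, d))
            q, _ = pca_profile(X, 0.95)
            cov = np.cov(X - X.mean(axis=0), rowvar=False)
            evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
            cum = np.cumsum(evals) / evals.sum()
            oracle = int(np.searchsorted(cum, 0.95 - 1e-12) + 1)
            assert q == oracle

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant|variance"):
            pca_profile(np.ones((10, 3)), 0.95)

    def test_variance_target_validated(self):
        with pytest.raises(ValueError):
            pca_profile(np.random.default_rng(0).standard_normal((10, 3)), 1.5)


def _report(values: dict[str, dict[str, list[float]]], metric="map10"):
    rows = []
    for setting, modes in values.items():
        for mode, vals in modes.items():
            for r, v in enumerate(vals):
                rows.append(
                    {"setting": setting, "mode": mode, "repeat": r,
                     "map10": v, "weighted_f1": v}
                )
    return EvalReport(records=pd.DataFrame(rows), settings=tuple(values))


class TestSummarizeImprovement:
    def test_identical_metrics_give_zero_delta(self):
        rep = _report({
            "e+ap": {"keep-target": [0.5, 0.5], "passthrough": [0.5, 0.5]},
        })
        assert summarize_improvement(rep)["absolute"] == pytest.approx(0.0)

    def test_missing_setting_rejected(self):
        rep = _report({"e+ap": {"keep-target": [0.5], "passthrough": [0.4]}})
        rep = EvalReport(records=rep.records, settings=("e+ap", "e+hp"))
        with pytest.raises(ValueError, match="missing"):
            summarize_improvement(rep)

    def test_hand_built_deltas_average_correctly(self):
        rep = _report({
            "e+ap": {"keep-target": [0.6, 0.62], "passthrough": [0.5, 0.52]},
            "e+hp": {"keep-target": [0.7, 0.72], "passthrough": [0.66, 0.68]},
        })
        out = summarize_improvement(rep)
        assert out["absolute"] == pytest.approx((0.1 + 0.04) / 2)
        assert out["relative"] == pytest.approx(
            (0.1 / 0.51 + 0.04 / 0.67) / 2
        )


class TestRunSetting:
    def _toy(self):
        spec = CohortSpec(
            n_slides=16, classes=("a", "b"), class_priors=(0.5, 0.5),
            feature_dim=8, bag_size_range=(8, 12), seed=21,
        )
        return generate_cohort(spec)

    def test_smoke_passthrough_ap(self):
        cohort = self._toy()
        res = run_setting(
            cohort.bags, cohort.labels_by_slide,
            SplitPlan(repeats=2, base_seed=1),
            bpg_mode="passthrough", pooling="ap",
            knn_config=KNNConfig(k_grid=(1, 3), inner_cv_folds=2),
        )
        assert len(res) == 2
        for r in res:
            assert 0.0 <= r["map10"] <= 1.0
            assert 0.0 <= r["weighted_f1"] <= 1.0

    def test_all_signal_bags_make_filter_a_noop(self):
        spec = CohortSpec(
            n_slides=16, classes=("a", "b"), class_priors=(0.5, 0.5),
            feature_dim=8, bag_size_range=(8, 12),
            noise_fraction_range=(0.0, 0.0), seed=22,
        )
        cohort = generate_cohort(spec)
        # centroid 1 sits far away at the would-be noise location
        far = np.zeros(8)
        far[3] = 100.0
        model = designate_target(
            BPGModel(np.vstack([np.zeros(8), far]), extractor_name="synthetic"), 0
        )
        knn = KNNConfig(k_grid=(1, 3), inner_cv_folds=2)
        plan = SplitPlan(repeats=2, base_seed=3)
        args = (cohort.bags, cohort.labels_by_slide, plan)
        filtered = run_setting(*args, bpg_model=model, bpg_mode="keep-target",
                               pooling="ap", knn_config=knn)
        baseline = run_setting(*args, bpg_model=model, bpg_mode="passthrough",
                               pooling="ap", knn_config=knn)
        assert filtered == baseline

    def test_requires_designated_model_for_filtering(self):
        cohort = self._toy()
        with pytest.raises(ValueError, match="designated"):
            run_setting(
                cohort.bags, cohort.labels_by_slide, SplitPlan(repeats=1),
                bpg_model=None, bpg_mode="keep-target",
            )

    def test_report_reproducible(self):
        cohort = self._toy()
        knn = KNNConfig(k_grid=(1, 3), inner_cv_folds=2)
        plan = SplitPlan(repeats=2, base_seed=7)
        hp = TrainingConfig(epochs=2, query_dim=4, seed=11)
        a = run_setting(cohort.bags, cohort.labels_by_slide, plan,
                        pooling="hp", hp_config=hp, knn_config=knn)
        b = run_setting(cohort.bags, cohort.labels_by_slide, plan,
                        pooling="hp", hp_config=hp, knn_config=knn)
        assert a == b
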