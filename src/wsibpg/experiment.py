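"""Monte-Carlo cross-validation harness for the slide-representation study.

The evaluation design is repeated stratified 50/50 splitting (default five
repeats): per repeat each class is shuffled independently and halved, with
an odd class's extra slide going to the test half, so a 633-slide cohort
splits 316/317. Every (extractor x pooling x patch-filter mode) setting is
scored on identical splits, which makes the per-repeat metric differences
paired; improvements are tested with a one-tailed paired t test (H1: mean
difference > 0), with an exact sign-flip permutation variant for small
repeat counts. The overall effect of the filtering stage is summarized as
the mean of improvements across settings. A PCA profile (components needed
to reach a variance target, default 95%) characterizes the variability of
each extractor's feature space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .bpg import BPGModel, apply_bpg, build_profiling_set, designate_target, fit_bpg, present_reference
from .classify import KNNConfig, knn_fit_predict, weighted_scores
from .features import PatchBag
from .pooling import TrainingConfig, average_pool, hopfield_pool, train_pooling
from .retrieval import evaluate_retrieval

__all__ = [
    "SplitPlan",
    "EvalReport",
    "make_splits",
    "run_setting",
    "run_study",
    "paired_one_tailed",
    "pca_profile",
    "summarize_improvement",
    "prepare_bpg_from_truth",
]

MODES = ("keep-target", "passthrough", "keep-nontarget")


@dataclass(frozen=True)
class SplitPlan:
    """Monte-Carlo cross-validation plan: per-repeat seeds, 50/50 default."""

    repeats: int = 5
    train_fraction: float = 0.5
    seeds: tuple[int, ...] | None = None
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.seeds is None:
            object.__setattr__(
                self,
                "seeds",
                tuple(self.base_seed + 7919 * r for r in range(self.repeats)),
            )
        elif len(self.seeds) != self.repeats:
            raise ValueError("need one seed per repeat")


def make_splits(
    labels: Mapping[str, str], plan: SplitPlan
) -> list[tuple[list[str], list[str]]]:
    """Stratified random train/test partitions, one per repeat.

    Each class is shuffled and split independently at ``train_fraction``
    (floor), the remainder going to the test half; splits are disjoint,
    exhaustive, and per-class proportions stay within one slide of the
    overall fraction.
    """
    by_class: dict[str, list[str]] = {}
    for sid, lab in labels.items():
        by_class.setdefault(lab, []).append(sid)
    for lab, members in by_class.items():
        if len(members) < 2:
            raise ValueError(f"class {lab!r} has a single slide; cannot split")
    splits = []
    for seed in plan.seeds:
        rng = np.random.default_rng(seed)
        train, test = [], []
        for lab in sorted(by_class):
            members = sorted(by_class[lab])
            rng.shuffle(members)
            n_train = int(len(members) * plan.train_fraction)
            train.extend(members[:n_train])
            test.extend(members[n_train:])
        splits.append((sorted(train), sorted(test)))
    return splits


def prepare_bpg_from_truth(
    bags: Sequence[PatchBag],
    patch_truth: Sequence[np.ndarray],
    n_per_slide: int = 96,
    seed: int = 0,
) -> tuple[BPGModel, str]:
    """Fit the two-group patch clustering and stand in for the pathologist.

    A reference slide is chosen at random and excluded from the profiling
    sample; after the k=2 fit, the reference slide's patches are assigned
    to the two clusters and the cluster holding the majority of the
    slide's ground-truth signal patches is designated as the target —
    exactly the judgement an expert makes from the two patch groups.
    Returns the designated model and the reference slide id.
    """
    rng = np.random.default_rng(seed)
    ref_pos = int(rng.integers(len(bags)))
    ref_bag = bags[ref_pos]
    profiling = build_profiling_set(
        bags, n_per_slide=n_per_slide, exclude_slide=ref_bag.slide_id, seed=seed
    )
    model = fit_bpg(profiling, seed=seed, reference_slide_id=ref_bag.slide_id)
    g0, g1 = present_reference(model, ref_bag)
    truth = np.asarray(patch_truth[ref_pos], dtype=bool)
    signal_ids = {p for p, s in zip(ref_bag.patch_ids, truth) if s}
    votes0 = sum(p in signal_ids for p in g0)
    votes1 = sum(p in signal_ids for p in g1)
    chosen = 0 if votes0 >= votes1 else 1
    return (
        designate_target(model, chosen, note="majority-signal cluster of reference"),
        ref_bag.slide_id,
    )


def run_setting(
    bags: Sequence[PatchBag],
    labels: Mapping[str, str],
    plan: SplitPlan,
    bpg_model: BPGModel | None = None,
    bpg_mode: str = "passthrough",
    pooling: str = "ap",
    hp_config: TrainingConfig | None = None,
    knn_config: KNNConfig = KNNConfig(),
    map_at: int = 10,
) -> list[dict]:
    """Score one (filter mode x pooling) setting across all CV repeats.

    Per repeat: bags are filtered by the designated clustering model,
    pooled into slide vectors (the attention pooler is retrained on the
    repeat's training half only), then scored by leave-one-out test-set
    retrieval (mAP@``map_at``) and train-to-test weighted k-NN
    classification (weighted-F1). The filtering model itself is fit once,
    globally — its preparation is independent of the representation
    pipeline, so no per-split refit is needed.
    """
    if pooling not in ("ap", "hp"):
        raise ValueError("pooling must be 'ap' or 'hp'")
    if bpg_mode != "passthrough" and (bpg_model is None or not bpg_model.is_designated):
        raise ValueError("a designated BPG model is required for filtering modes")
    if bpg_mode == "passthrough":
        filtered = {b.slide_id: b for b in bags}
    else:
        filtered = {b.slide_id: apply_bpg(bpg_model, b, bpg_mode) for b in bags}
    splits = make_splits(labels, plan)
    hp_config = hp_config or TrainingConfig(epochs=20)

    results = []
    for r, (train_ids, test_ids) in enumerate(splits):
        if pooling == "hp":
            cfg = replace(hp_config, seed=hp_config.seed + r)
            model = train_pooling(
                [filtered[s] for s in train_ids],
                [labels[s] for s in train_ids],
                cfg,
            )
            vectors = {s: hopfield_pool(model, filtered[s]) for s in filtered}
        else:
            vectors = {s: average_pool(filtered[s]) for s in filtered}

        map10 = evaluate_retrieval(
            [vectors[s] for s in test_ids], dict(labels), n=map_at
        )
        preds, chosen_k = knn_fit_predict(
            [vectors[s] for s in train_ids],
            [labels[s] for s in train_ids],
            [vectors[s] for s in test_ids],
            knn_config,
        )
        report = weighted_scores([labels[s] for s in test_ids], preds)
        results.append(
            {
                "repeat": r,
                "map10": map10,
                "weighted_f1": report.weighted_f1,
                "chosen_k": chosen_k,
            }
        )
    return results


@dataclass
class EvalReport:
    """Per-(setting, mode, repeat) metrics plus the settings it must cover."""

    records: pd.DataFrame  # columns: setting, mode, repeat, map10, weighted_f1
    settings: tuple[str, ...]
    modes: tuple[str, ...] = MODES

    def mean_sd(self) -> pd.DataFrame:
        return (
            self.records.groupby(["setting", "mode"])[["map10", "weighted_f1"]]
            .agg(["mean", "std"])
        )

    def paired_deltas(
        self, metric: str, mode_a: str = "keep-target", mode_b: str = "passthrough"
    ) -> dict[str, np.ndarray]:
        """Per-setting arrays of per-repeat differences metric(a) - metric(b);
        both modes were evaluated on identical splits, so the differences
        are paired."""
        out = {}
        for setting in self.settings:
            sub = self.records[self.records.setting == setting]
            a = sub[sub["mode"] == mode_a].sort_values("repeat")[metric].to_numpy()
            b = sub[sub["mode"] == mode_b].sort_values("repeat")[metric].to_numpy()
            if len(a) != len(b) or len(a) == 0:
                raise ValueError(f"setting {setting!r} missing repeats for pairing")
            out[setting] = a - b
        return out

    def p_values(
        self, metric: str, mode_a: str = "keep-target", mode_b: str = "passthrough"
    ) -> dict[str, float]:
        return {
            s: paired_one_tailed(d)
            for s, d in self.paired_deltas(metric, mode_a, mode_b).items()
        }


def run_study(
    bags: Sequence[PatchBag],
    labels: Mapping[str, str],
    plan: SplitPlan,
    bpg_model: BPGModel,
    poolings: Sequence[str] = ("ap", "hp"),
    modes: Sequence[str] = MODES,
    hp_config: TrainingConfig | None = None,
    knn_config: KNNConfig = KNNConfig(),
) -> EvalReport:
    """Evaluate every (pooling x filter mode) combination on shared splits."""
    extractor = bags[0].extractor_name
    rows = []
    for pooling, mode in product(poolings, modes):
        setting = f"{extractor}+{pooling}"
        for rec in run_setting(
            bags, labels, plan,
            bpg_model=bpg_model, bpg_mode=mode, pooling=pooling,
            hp_config=hp_config, knn_config=knn_config,
        ):
            rows.append({"setting": setting, "mode": mode, **rec})
    return EvalReport(
        records=pd.DataFrame(rows),
        settings=tuple(f"{extractor}+{p}" for p in poolings),
        modes=tuple(modes),
    )


def paired_one_tailed(deltas: Sequence[float], method: str = "t") -> float:
    """One-tailed test of H1: mean paired difference > 0.

    ``method='t'`` is a paired t test on the differences;
    ``method='permutation'`` enumerates all sign flips exactly (feasible
    for up to ~12 pairs). Zero-variance differences short-circuit by
    convention: all positive -> 0, all negative -> 1, all zero -> error.
    """
    d = np.asarray(list(deltas), dtype=np.float64)
    if d.size < 2:
        raise ValueError("need at least two paired differences")
    if np.all(d == 0):
        raise ValueError("all paired differences are exactly zero")
    if d.std() == 0:
        return 0.0 if d[0] > 0 else 1.0
    if method == "t":
        return float(stats.ttest_1samp(d, 0.0, alternative="greater").pvalue)
    if method == "permutation":
        if d.size > 12:
            raise ValueError("exact permutation supported for <= 12 pairs")
        observed = d.mean()
        count = 0
        for mask in range(2 ** d.size):
            signs = np.array(
                [1.0 if mask & (1 << i) else -1.0 for i in range(d.size)]
            )
            if (signs * d).mean() >= observed - 1e-15:
                count += 1
        return count / 2 ** d.size
    raise ValueError(f"unknown method {method!r}")


def pca_profile(
    features: np.ndarray, variance_target: float = 0.95
) -> tuple[int, float]:
    """Components needed to explain ``variance_target`` of the variance.

    Returns ``(q, q/d)`` where q is the smallest component count whose
    cumulative explained-variance ratio reaches the target.
    """
    X = np.asarray(features, dtype=np.float64)
    if not (0.0 < variance_target < 1.0):
        raise ValueError("variance_target must lie in (0, 1)")
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("features must be an (n>=2, d) matrix")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("constant feature matrix has no variance to explain")
    pca = PCA(svd_solver="full").fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    q = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    return q, q / X.shape[1]


def summarize_improvement(
    report: EvalReport,
    metric: str = "map10",
    mode_a: str = "keep-target",
    mode_b: str = "passthrough",
) -> dict[str, float]:
    """Mean improvement of mode_a over mode_b across all declared settings.

    Every setting the report declares must be present (a missing one is an
    error, not a silent skip). Returns the absolute mean delta and the
    relative improvement against the mode_b mean.
    """
    present = set(report.records["setting"].unique())
    missing = [s for s in report.settings if s not in present]
    if missing:
        raise ValueError(f"settings missing from report: {missing}")
    deltas = report.paired_deltas(metric, mode_a, mode_b)
    per_setting = np.array([d.mean() for d in deltas.values()])
    base = np.array(
        [
            report.records[
                (report.records.setting == s) & (report.records["mode"] == mode_b)
            ][metric].mean()
            for s in report.settings
        ]
    )
    absolute = float(per_setting.mean())
    relative = float((per_setting / base).mean())
    return {"absolute": absolute, "relative": relative}
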