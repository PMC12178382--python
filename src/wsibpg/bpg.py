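"""Binary patch grouping (BPG): k=2 patch filtering with one-time human input.

The stage is prepared once for a cohort and a fixed feature extractor:

1. ``build_profiling_set`` pools up to ``n_per_slide`` (default 96) randomly
   sampled patch feature vectors from every slide except one randomly chosen
   *reference* slide. Slides with fewer patches contribute all of them. No
   slide-level quality filter applies here — profiling is independent of the
   representation pipeline.
2. ``fit_bpg`` clusters the pooled sample into two groups with standard
   k-means (k = 2, Euclidean, multiple restarts, best inertia).
3. ``present_reference`` assigns the held-out reference slide's patches to
   the two centroids so a pathologist can inspect both groups, and
   ``designate_target`` records which group is diagnostically relevant —
   the single human interaction in the whole lifecycle.
4. ``apply_bpg`` then filters any bag by nearest-centroid assignment:
   keep-target is BPG proper, keep-nontarget is the complementary BPG-
   control, passthrough is the no-filtering baseline.

k is fixed at 2 by design: the stage separates a signal population from a
noise population (tissue vs bone/fat/blank); more clusters would fragment
the signal boundary rather than sharpen it. Patches are assigned with the
profiling centroids, never by re-clustering per slide — a fresh per-slide
k-means would break the one-time designation contract, since cluster
identities would not transfer across slides.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .features import PatchBag

__all__ = [
    "ProfilingSet",
    "BPGModel",
    "build_profiling_set",
    "fit_bpg",
    "present_reference",
    "designate_target",
    "apply_bpg",
    "save_model",
    "load_model",
]

BPGMode = Literal["keep-target", "keep-nontarget", "passthrough"]


@dataclass
class ProfilingSet:
    """Pooled patch-feature sample used to fit the two-group clustering."""

    features: np.ndarray  # (m, d)
    source: list[tuple[str, str]]  # (slide_id, patch_id) per row
    sample_size_per_slide: int
    seed: int
    extractor_name: str = "unknown"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise ValueError("profiling features must be an (m, d) matrix")
        if len(self.source) != self.features.shape[0]:
            raise ValueError("source rows must align with features")


@dataclass
class BPGModel:
    centroids: np.ndarray  # (2, d)
    target_index: int | None = None
    reference_slide_id: str = ""
    fit_seed: int = 0
    extractor_name: str = "unknown"
    designation_note: str = ""
    designated_at: str = ""

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=np.float64)
        if self.centroids.shape[0] != 2 or self.centroids.ndim != 2:
            raise ValueError("a BPG model has exactly two centroids")
        if self.target_index is not None and self.target_index not in (0, 1):
            raise ValueError("target_index must be 0 or 1")

    @property
    def is_designated(self) -> bool:
        return self.target_index is not None

    def assign(self, features: np.ndarray) -> np.ndarray:
        """Nearest-centroid label (0/1) per row; ties go to index 0."""
        X = np.asarray(features, dtype=np.float64)
        if X.shape[1] != self.centroids.shape[1]:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match model "
                f"dimension {self.centroids.shape[1]}"
            )
        d0 = np.linalg.norm(X - self.centroids[0], axis=1)
        d1 = np.linalg.norm(X - self.centroids[1], axis=1)
        return (d1 < d0).astype(int)  # tie (d1 == d0) -> 0


def build_profiling_set(
    bags: Sequence[PatchBag],
    n_per_slide: int = 96,
    exclude_slide: str | None = None,
    seed: int = 0,
) -> ProfilingSet:
    """Sample up to ``n_per_slide`` patch features per slide, without
    replacement, skipping the reference slide.

    ``n_per_slide`` defaults to 96, an empirically adequate per-slide
    sample; slides with fewer patches contribute everything they have.
    """
    if len(bags) == 0:
        raise ValueError("bags must be nonempty")
    ids = [b.slide_id for b in bags]
    if exclude_slide is not None and exclude_slide not in ids:
        raise ValueError(f"exclude_slide {exclude_slide!r} not found in bags")
    rng = np.random.default_rng(seed)
    rows, source = [], []
    extractor = bags[0].extractor_name
    for bag in bags:
        if bag.slide_id == exclude_slide:
            continue
        if bag.extractor_name != extractor:
            raise ValueError("all bags must come from the same extractor")
        if bag.n_patches <= n_per_slide:
            idx = np.arange(bag.n_patches)
        else:
            idx = rng.choice(bag.n_patches, size=n_per_slide, replace=False)
            idx.sort()
        rows.append(bag.features[idx])
        source.extend((bag.slide_id, bag.patch_ids[i]) for i in idx)
    return ProfilingSet(
        features=np.vstack(rows),
        source=source,
        sample_size_per_slide=n_per_slide,
        seed=seed,
        extractor_name=extractor,
    )


def fit_bpg(
    profiling: ProfilingSet,
    seed: int = 0,
    n_restarts: int = 10,
    reference_slide_id: str = "",
) -> BPGModel:
    """Fit the two-group k-means on the profiling set (target unset).

    Standard Lloyd iterations, Euclidean metric on the raw feature space
    (no scaling — the extractor's geometry is taken as-is), ``n_restarts``
    random initialisations with the best-inertia solution kept.
    """
    X = profiling.features
    if X.shape[0] < 2:
        raise ValueError("need at least two profiling rows to cluster")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate profiling data: all rows identical")
    km = KMeans(
        n_clusters=2,
        n_init=n_restarts,
        init="random",
        algorithm="lloyd",
        random_state=seed,
    ).fit(X)
    return BPGModel(
        centroids=km.cluster_centers_,
        target_index=None,
        reference_slide_id=reference_slide_id,
        fit_seed=seed,
        extractor_name=profiling.extractor_name,
    )


def present_reference(
    model: BPGModel, reference_bag: PatchBag
) -> tuple[list[str], list[str]]:
    """Split the reference slide's patches into the two cluster groups.

    Returns the patch-id lists ``(group_0, group_1)`` for human inspection
    (montage export lives in the CLI when rasters are available). Together
    the groups partition the bag.
    """
    if model.extractor_name not in ("unknown", reference_bag.extractor_name):
        raise ValueError(
            "reference bag extractor does not match the fitted model"
        )
    assignment = model.assign(reference_bag.features)
    g0 = [p for p, a in zip(reference_bag.patch_ids, assignment) if a == 0]
    g1 = [p for p, a in zip(reference_bag.patch_ids, assignment) if a == 1]
    return g0, g1


def designate_target(
    model: BPGModel, chosen_index: int, note: str = "", overwrite: bool = False
) -> BPGModel:
    """Record the human choice of the diagnostically relevant cluster.

    This is the one-time expert intervention; it is stamped with a UTC time
    and optional annotator note. Re-designation must be explicit
    (``overwrite=True``).
    """
    if chosen_index not in (0, 1):
        raise ValueError("chosen_index must be 0 or 1")
    if model.is_designated and not overwrite:
        raise ValueError("target already designated; pass overwrite=True to change it")
    return BPGModel(
        centroids=model.centroids.copy(),
        target_index=int(chosen_index),
        reference_slide_id=model.reference_slide_id,
        fit_seed=model.fit_seed,
        extractor_name=model.extractor_name,
        designation_note=note,
        designated_at=datetime.now(timezone.utc).isoformat(),
    )


def apply_bpg(model: BPGModel, bag: PatchBag, mode: BPGMode = "keep-target") -> PatchBag:
    """Filter a bag to its target (or nontarget) cluster patches.

    ``keep-target`` is BPG proper; ``keep-nontarget`` keeps the complement
    (the BPG- control); ``passthrough`` returns the bag unchanged (the
    no-filtering baseline). If the kept set would be empty, the whole bag
    is returned with a warning — every slide must yield a representation.
    """
    if mode == "passthrough":
        return bag
    if mode not in ("keep-target", "keep-nontarget"):
        raise ValueError(f"unknown mode {mode!r}")
    if not model.is_designated:
        raise ValueError("BPG target has not been designated")
    assignment = model.assign(bag.features)
    wanted = model.target_index if mode == "keep-target" else 1 - model.target_index
    keep = np.flatnonzero(assignment == wanted)
    if keep.size == 0:
        warnings.warn(
            f"slide {bag.slide_id}: no patches in the {mode} set; "
            "falling back to the unfiltered bag",
            stacklevel=2,
        )
        return bag
    return bag.subset(keep)


def save_model(model: BPGModel, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps(
            {
                "centroids": model.centroids.tolist(),
                "target_index": model.target_index,
                "reference_slide_id": model.reference_slide_id,
                "fit_seed": model.fit_seed,
                "extractor_name": model.extractor_name,
                "designation_note": model.designation_note,
                "designated_at": model.designated_at,
            },
            indent=2,
        )
    )
    return path


def load_model(path: str | Path) -> BPGModel:
    data = json.loads(Path(path).read_text())
    return BPGModel(
        centroids=np.asarray(data["centroids"]),
        target_index=data["target_index"],
        reference_slide_id=data["reference_slide_id"],
        fit_seed=data["fit_seed"],
        extractor_name=data["extractor_name"],
        designation_note=data.get("designation_note", ""),
        designated_at=data.get("designated_at", ""),
    )
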