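"""Patch feature extraction and the per-slide feature-bag container.

A *bag* is the multiple-instance-learning view of one slide: an ``(n, d)``
matrix whose rows are patch feature vectors. Deep backbones (DenseNet-121,
KimiaNet, HIPT ViT-16/256, DINO ViT-S/16) plug in through the extractor
registry; their pretrained weights are external artifacts and are never
bundled. A deterministic handcrafted extractor (channel histograms +
local-variance statistics pushed through a frozen random projection) is
built in so every downstream stage can run without any model download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import h5py
import numpy as np
from scipy import ndimage

__all__ = [
    "PatchBag",
    "FeatureExtractor",
    "BuiltinExtractor",
    "get_extractor",
    "register_extractor",
    "extract_features",
    "save_bag",
    "load_bag",
    "write_cohort_index",
    "read_cohort_index",
]


@dataclass
class PatchBag:
    """One slide's patch feature vectors plus aligned patch identifiers."""

    slide_id: str
    features: np.ndarray  # (n_patches, d) float32
    patch_ids: list[str]
    extractor_name: str = "unknown"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float32)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D (n_patches, d) matrix")
        if self.features.shape[0] < 1:
            raise ValueError("a bag must contain at least one patch")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain NaN or Inf")
        self.patch_ids = [str(p) for p in self.patch_ids]
        if len(self.patch_ids) != self.features.shape[0]:
            raise ValueError(
                f"patch_ids ({len(self.patch_ids)}) do not align with "
                f"feature rows ({self.features.shape[0]})"
            )

    @property
    def n_patches(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]

    def subset(self, row_indices: np.ndarray) -> "PatchBag":
        """New bag restricted to the given rows (order preserved)."""
        idx = np.asarray(row_indices, dtype=int)
        return PatchBag(
            slide_id=self.slide_id,
            features=self.features[idx],
            patch_ids=[self.patch_ids[i] for i in idx],
            extractor_name=self.extractor_name,
        )


class FeatureExtractor(Protocol):
    """Anything that maps a list of RGB tiles to an (n, d) float matrix."""

    name: str
    dim: int

    def __call__(self, tiles: Sequence[np.ndarray]) -> np.ndarray: ...


# frozen seed for the random-projection stage; part of the extractor
# definition, never user-configurable (purity contract)
_PROJECTION_SEED = 0x5EED


@dataclass
class BuiltinExtractor:
    """Deterministic handcrafted patch featurizer.

    Concatenates per-channel intensity histograms, local-standard-deviation
    summary statistics and global moments, then applies a fixed Gaussian
    random projection (frozen seed) to the configured output length. Pure:
    identical tile bytes always give identical rows.

    The default output length of 384 matches the vision-transformer
    backbones, which keeps PCA variance profiling comparable across
    extractors.
    """

    dim: int = 384
    n_bins: int = 16
    name: str = field(init=False)

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        self.name = f"builtin-d{self.dim}"

    def _raw_descriptor(self, tile: np.ndarray) -> np.ndarray:
        tile = _as_rgb(tile)
        x = tile.astype(np.float32) / 255.0
        parts: list[np.ndarray] = []
        for c in range(3):
            hist, _ = np.histogram(x[:, :, c], bins=self.n_bins, range=(0.0, 1.0))
            parts.append(hist.astype(np.float32) / x[:, :, c].size)
        gray = x.mean(axis=2)
        mu = ndimage.uniform_filter(gray, size=8)
        mu2 = ndimage.uniform_filter(gray * gray, size=8)
        local_sd = np.sqrt(np.maximum(mu2 - mu * mu, 0.0))
        gy, gx = np.gradient(gray)
        grad_mag = np.hypot(gx, gy)
        stats = np.array(
            [
                gray.mean(), gray.std(),
                local_sd.mean(), local_sd.std(), local_sd.max(),
                grad_mag.mean(), grad_mag.std(),
                x[:, :, 0].mean(), x[:, :, 1].mean(), x[:, :, 2].mean(),
                x[:, :, 0].std(), x[:, :, 1].std(), x[:, :, 2].std(),
            ],
            dtype=np.float32,
        )
        parts.append(stats)
        return np.concatenate(parts)

    def __call__(self, tiles: Sequence[np.ndarray]) -> np.ndarray:
        if len(tiles) == 0:
            return np.zeros((0, self.dim), dtype=np.float32)
        raw = np.stack([self._raw_descriptor(t) for t in tiles])
        rng = np.random.default_rng(_PROJECTION_SEED)
        proj = rng.standard_normal((raw.shape[1], self.dim)).astype(np.float32)
        proj /= np.sqrt(raw.shape[1])
        return (raw @ proj).astype(np.float32)


def _as_rgb(tile: np.ndarray) -> np.ndarray:
    tile = np.asarray(tile)
    if tile.ndim != 3 or tile.shape[2] != 3:
        raise ValueError("tile must be an (H, W, 3) RGB raster")
    return tile


_EXTRACTORS: dict[str, FeatureExtractor] = {}


def register_extractor(extractor: FeatureExtractor) -> None:
    _EXTRACTORS[extractor.name] = extractor


def get_extractor(name: str) -> FeatureExtractor:
    """Resolve an extractor by name.

    Deep-backbone adapters are looked up here too; if a named backbone has
    not been registered (e.g. its weights are not available) this raises a
    capability error rather than silently falling back.
    """
    if name in _EXTRACTORS:
        return _EXTRACTORS[name]
    if name.startswith("builtin"):
        dim = int(name.split("-d")[1]) if "-d" in name else 384
        ex = BuiltinExtractor(dim=dim)
        register_extractor(ex)
        return ex
    raise LookupError(
        f"feature extractor {name!r} is not available; deep backbones must be "
        "registered explicitly with register_extractor()"
    )


def extract_features(
    tiles: Sequence[np.ndarray],
    extractor: FeatureExtractor | str,
    slide_id: str = "slide",
    patch_ids: Sequence[str] | None = None,
) -> PatchBag:
    """Run an extractor over tiles and assemble the slide's bag.

    All tiles must share a size. Rows align with ``patch_ids`` (defaulting
    to the tile position index).
    """
    if isinstance(extractor, str):
        extractor = get_extractor(extractor)
    if len(tiles) == 0:
        raise ValueError("cannot extract features from an empty tile list")
    shapes = {t.shape for t in map(np.asarray, tiles)}
    if len(shapes) > 1:
        raise ValueError(f"tiles have mixed shapes: {sorted(shapes)}")
    feats = extractor(tiles)
    if patch_ids is None:
        patch_ids = [str(i) for i in range(len(tiles))]
    return PatchBag(
        slide_id=slide_id,
        features=feats,
        patch_ids=list(patch_ids),
        extractor_name=extractor.name,
    )


# ---------------------------------------------------------------------------
# feature-bag container: one HDF5 file per slide with a JSON manifest attr
# ---------------------------------------------------------------------------

def save_bag(bag: PatchBag, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "slide_id": bag.slide_id,
        "extractor_name": bag.extractor_name,
        "d": bag.dim,
        "patch_ids": bag.patch_ids,
    }
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=bag.features.astype(np.float32))
        f.attrs["manifest"] = json.dumps(manifest)
    return path


def load_bag(path: str | Path) -> PatchBag:
    with h5py.File(path, "r") as f:
        feats = f["features"][:]
        manifest = json.loads(f.attrs["manifest"])
    return PatchBag(
        slide_id=manifest["slide_id"],
        features=feats,
        patch_ids=manifest["patch_ids"],
        extractor_name=manifest["extractor_name"],
    )


def write_cohort_index(
    directory: str | Path,
    bag_paths: dict[str, str | Path],
    labels: dict[str, str] | None = None,
) -> Path:
    """Write the cohort index JSON listing bag files and slide labels."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = {
        "slides": [
            {
                "slide_id": sid,
                "bag_path": str(Path(p)),
                "label": None if labels is None else labels.get(sid),
            }
            for sid, p in sorted(bag_paths.items())
        ]
    }
    out = directory / "cohort_index.json"
    out.write_text(json.dumps(index, indent=2))
    return out


def read_cohort_index(path: str | Path) -> tuple[list[PatchBag], dict[str, str]]:
    index = json.loads(Path(path).read_text())
    bags, labels = [], {}
    for entry in index["slides"]:
        bags.append(load_bag(entry["bag_path"]))
        if entry.get("label") is not None:
            labels[entry["slide_id"]] = entry["label"]
    return bags, labels
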