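"""Tiling, patch exclusion and diagnostic-label simplification.

Slides are cut into a non-overlapping grid of fixed-size tiles (512x512 at
x40 in the reference workflow). Two exclusion rules remove patches without
tissue: a blankness rule on RGB values (fraction of near-white pixels) and
a low-content rule. The low-content rule is, at heart, a compressibility
heuristic — tiles whose compressed file size falls below ~80 KB hold no
tissue fragment — so when a tile originates from a file the byte size is
used directly; for in-memory rasters a mean local-standard-deviation proxy
with its own calibrated threshold stands in, since file size depends on the
storage dialect.

Slides retaining fewer than a minimum number of patches (default 64) are
dropped entirely, and free-text multilabel diagnoses are simplified to six
classes by a priority rule list.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence
import warnings

import numpy as np
from scipy import ndimage

from .features import PatchBag

__all__ = [
    "PatchRecord",
    "SlideLabel",
    "tile_image",
    "filter_blank",
    "filter_low_content",
    "filter_slides",
    "simplify_labels",
    "DEFAULT_KEYWORD_MAP",
    "UNMAPPED",
]


@dataclass(frozen=True)
class PatchRecord:
    """Grid position of one tile. Coordinates are 0-based pixel offsets of
    the tile origin (x = column, y = row), half-open extents."""

    slide_id: str
    x: int
    y: int
    width: int
    height: int
    content_score: float = float("nan")

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError("tile origin must be nonnegative")
        if self.width != self.height:
            raise ValueError("tiles are square")


@dataclass(frozen=True)
class SlideLabel:
    slide_id: str
    raw_labels: tuple[str, ...]
    simplified: str


def tile_image(
    image: np.ndarray,
    tile_size: int = 512,
    slide_id: str = "slide",
    magnification_tag: str = "40x",
) -> tuple[list[PatchRecord], list[np.ndarray]]:
    """Cut an RGB raster into a non-overlapping row-major grid of tiles.

    Partial tiles at the right/bottom edges are discarded. An image smaller
    than one tile yields an empty list with a warning.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be an (H, W, 3) RGB raster")
    H, W = image.shape[:2]
    if H < tile_size or W < tile_size:
        warnings.warn(
            f"image ({W}x{H}) smaller than one {tile_size}px tile; no tiles",
            stacklevel=2,
        )
        return [], []
    records, rasters = [], []
    for y in range(0, (H // tile_size) * tile_size, tile_size):
        for x in range(0, (W // tile_size) * tile_size, tile_size):
            records.append(
                PatchRecord(slide_id=slide_id, x=x, y=y,
                            width=tile_size, height=tile_size)
            )
            rasters.append(image[y : y + tile_size, x : x + tile_size])
    return records, rasters


def filter_blank(
    tile: np.ndarray,
    blank_threshold: float = 0.5,
    whiteness_cutoff: int = 220,
) -> tuple[bool, float]:
    """Blankness rule on RGB values.

    A pixel is near-white when all three channels are >= ``whiteness_cutoff``
    (default 220/255). The tile is dropped when the near-white fraction
    strictly exceeds ``blank_threshold``. Returns ``(keep, content_score)``
    with content_score = 1 - near-white fraction.
    """
    tile = np.asarray(tile)
    if tile.ndim != 3 or tile.shape[2] != 3 or tile.dtype != np.uint8:
        raise ValueError("tile must be an 8-bit (H, W, 3) RGB raster")
    white = np.all(tile >= whiteness_cutoff, axis=2)
    frac = float(white.mean())
    return frac <= blank_threshold, 1.0 - frac


def _local_sd_score(tile: np.ndarray, window: int = 8) -> float:
    gray = np.asarray(tile, dtype=np.float64).mean(axis=2)
    mu = ndimage.uniform_filter(gray, size=window)
    mu2 = ndimage.uniform_filter(gray * gray, size=window)
    return float(np.sqrt(np.maximum(mu2 - mu * mu, 0.0)).mean())


def filter_low_content(
    tile: np.ndarray,
    min_size_proxy: float = 3.0,
    source_path: str | Path | None = None,
    min_file_bytes: int = 80 * 1024,
) -> tuple[bool, float]:
    """Low-content (compressibility) rule.

    When the tile came from a file, drop it if the file is smaller than
    ``min_file_bytes`` (default 80 KB). Otherwise use the mean local pixel
    standard deviation as a monotone content proxy and drop below
    ``min_size_proxy``. Returns ``(keep, proxy_value)``.
    """
    if source_path is not None:
        size = os.path.getsize(source_path)
        return size >= min_file_bytes, float(size)
    score = _local_sd_score(tile)
    return score >= min_size_proxy, score


def filter_slides(
    bags: Sequence[PatchBag], min_patches: int = 64
) -> tuple[list[PatchBag], list[str]]:
    """Retain bags with at least ``min_patches`` patches.

    Slides below the cutoff typically come from poor-quality glass and are
    disregarded. Returns ``(retained_bags, dropped_slide_ids)``.
    """
    if min_patches < 1:
        raise ValueError("min_patches must be >= 1")
    kept = [b for b in bags if b.n_patches >= min_patches]
    dropped = [b.slide_id for b in bags if b.n_patches < min_patches]
    return kept, dropped


UNMAPPED = "unmapped"

# priority-ordered class rules: a multilabel prediction simplifies to the
# first class whose keyword set intersects the labels
DEFAULT_KEYWORD_MAP: dict[str, tuple[str, ...]] = {
    "normal": ("normal",),
    "acute leukemia": (
        "acute leukemia",
        "acute myeloid leukemia",
        "acute lymphoblastic leukemia",
        "aml",
        "all",
    ),
    "myelodysplastic syndrome": ("myelodysplastic syndrome", "mds"),
    "plasma cell neoplasm": ("plasma cell neoplasm", "myeloma", "plasmacytoma"),
    "lymphoproliferative disorder": ("lymphoproliferative disorder", "lymphoma", "lpd"),
    "myeloproliferative neoplasm": ("myeloproliferative neoplasm", "mpn", "fibrosis"),
}


def simplify_labels(
    raw_labels: Iterable[str],
    keyword_map: dict[str, tuple[str, ...]] = DEFAULT_KEYWORD_MAP,
) -> str:
    """Simplify a multilabel diagnosis to one of six classes.

    Rules fire in the dict's priority order (normal first, then acute
    leukemia, myelodysplastic syndrome, plasma cell neoplasm,
    lymphoproliferative disorder, myeloproliferative neoplasm): the
    prediction simplifies to the first class any of whose keywords matches
    any label (case-insensitive substring, whole-token for short
    acronyms). Labels matching no rule map to the sentinel ``"unmapped"``;
    callers discard those slides as too rare to form a class.

    Descriptors such as "hypercellular" never decide a class on their own:
    they only accompany a class keyword.
    """
    labels = [str(l).strip().lower() for l in raw_labels]
    if not labels:
        raise ValueError("raw_labels must be nonempty")
    for cls, keywords in keyword_map.items():
        for kw in keywords:
            # word-boundary match so e.g. "abnormal" never matches "normal"
            pattern = rf"(?<!\w){re.escape(kw)}(?!\w)"
            if any(re.search(pattern, lab) for lab in labels):
                return cls
    return UNMAPPED
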