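"""Slide retrieval: vector index, Min-Max barcodes, ranking, mAP@n.

Given slide-level vectors, retrieval ranks the database by distance to a
query vector in ascending order and returns the top-n. Real vectors are
compared with cosine distance; optionally vectors are binarized into
barcode-style codes with the Min-Max rule (bit j = 1 iff v[j+1] > v[j]),
after which Hamming distance applies. Min-Max codes depend only on the
ordering of consecutive components, so any strictly monotone elementwise
transform leaves them unchanged.

Evaluation uses mean average precision at n with n = 10:

    mAP@n = (1/n) * sum_{i=1..n} P(i),
    P(i)  = precision at rank i when the i-th retrieval is correct, else 0,

averaged over queries, with each query's own vector excluded from its
result list (leave-one-out). Note the 1/n prefactor: this is precision at
the correct ranks divided by n, not by the number of relevant items.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .pooling import SlideVector
from .classify import cosine_distance

__all__ = [
    "RetrievalIndex",
    "RankedResult",
    "minmax_binarize",
    "build_index",
    "query",
    "mean_ap_at_n",
    "evaluate_retrieval",
]


@dataclass
class RetrievalIndex:
    vectors: np.ndarray          # (n, p) float or (n, p-1) uint8 codes
    slide_ids: list[str]
    labels: list[str]
    metric: str = "cosine"       # "cosine" | "hamming"

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors)
        if not (len(self.slide_ids) == len(self.labels) == self.vectors.shape[0]):
            raise ValueError("vectors, slide_ids and labels must align")
        if self.metric not in ("cosine", "hamming"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.metric == "hamming" and self.vectors.dtype != np.uint8:
            raise ValueError("hamming metric requires uint8 binary codes")
        if self.metric == "cosine" and self.vectors.dtype == np.uint8:
            raise ValueError("cosine metric expects real-valued vectors")

    def __len__(self) -> int:
        return self.vectors.shape[0]


@dataclass
class RankedResult:
    query_id: str
    ranked_ids: list[str]
    relevant: list[bool]  # per position: retrieved slide shares the query label
    distances: list[float]

    def __post_init__(self) -> None:
        if self.query_id in self.ranked_ids:
            raise ValueError("a query must be excluded from its own results")
        if not (len(self.ranked_ids) == len(self.relevant) == len(self.distances)):
            raise ValueError("ranked ids, flags and distances must align")


def minmax_binarize(vector: np.ndarray) -> np.ndarray:
    """Min-Max barcode: bit j = 1 iff v[j+1] > v[j] (ties give 0)."""
    v = np.asarray(vector, dtype=np.float64).ravel()
    if v.size < 2:
        raise ValueError("Min-Max binarization needs at least two components")
    return (np.diff(v) > 0).astype(np.uint8)


def build_index(
    slide_vectors: Sequence[SlideVector],
    labels: dict[str, str],
    binarize: bool = False,
) -> RetrievalIndex:
    """Assemble an index from slide vectors; optionally as Min-Max codes."""
    ids = [sv.slide_id for sv in slide_vectors]
    if binarize:
        mat = np.stack([minmax_binarize(sv.vector) for sv in slide_vectors])
        metric = "hamming"
    else:
        mat = np.stack([sv.vector for sv in slide_vectors])
        metric = "cosine"
    return RetrievalIndex(
        vectors=mat,
        slide_ids=ids,
        labels=[labels[i] for i in ids],
        metric=metric,
    )


def _distances(index: RetrievalIndex, q: np.ndarray) -> np.ndarray:
    if index.metric == "hamming":
        return (index.vectors != q[None, :]).sum(axis=1).astype(np.float64)
    return np.array([cosine_distance(q, row) for row in index.vectors])


def query(
    index: RetrievalIndex,
    q: SlideVector | np.ndarray,
    n: int = 10,
    query_id: str | None = None,
    query_label: str | None = None,
) -> RankedResult:
    """Rank the index by ascending distance to ``q`` and keep the top n.

    Ties in distance are broken by lexicographic slide id. When the query
    is itself a member of the index (matching id), it is left out of its
    own results. If n exceeds the index size, all available entries are
    returned without padding.
    """
    if len(index) == 0:
        raise ValueError("index is empty")
    if isinstance(q, SlideVector):
        qv, qid = q.vector, q.slide_id
    else:
        qv, qid = np.asarray(q), query_id
    if index.metric == "hamming" and qv.dtype != np.uint8:
        raise ValueError("binary index queried with a non-binary vector")
    if index.metric == "cosine" and qv.dtype == np.uint8:
        raise ValueError("real-vector index queried with a binary code")

    dist = _distances(index, qv)
    order = sorted(
        (i for i in range(len(index)) if index.slide_ids[i] != qid),
        key=lambda i: (dist[i], index.slide_ids[i]),
    )[:n]
    if query_label is None and qid is not None and qid in index.slide_ids:
        query_label = index.labels[index.slide_ids.index(qid)]
    return RankedResult(
        query_id=qid or "query",
        ranked_ids=[index.slide_ids[i] for i in order],
        relevant=[
            (query_label is not None) and (index.labels[i] == query_label)
            for i in order
        ],
        distances=[float(dist[i]) for i in order],
    )


def mean_ap_at_n(results: Sequence[RankedResult], n: int = 10) -> float:
    """Mean average precision at n over queries.

    Per query: P(i) = (# relevant in top i)/i when position i is relevant,
    else 0; the query's score is sum_i P(i) / n over positions 1..n.
    """
    if len(results) == 0:
        raise ValueError("no ranked results to score")
    scores = []
    for r in results:
        rel = r.relevant[:n]
        hits = 0
        total = 0.0
        for i, flag in enumerate(rel, start=1):
            if flag:
                hits += 1
                total += hits / i
        scores.append(total / n)
    return float(np.mean(scores))


def evaluate_retrieval(
    slide_vectors: Sequence[SlideVector],
    labels: dict[str, str],
    n: int = 10,
    binarize: bool = False,
) -> float:
    """Leave-one-out self-retrieval mAP@n over a set of slide vectors."""
    index = build_index(slide_vectors, labels, binarize=binarize)
    results = []
    for i, sid in enumerate(index.slide_ids):
        qv = index.vectors[i]
        results.append(
            query(index, qv, n=n, query_id=sid, query_label=index.labels[i])
        )
    return mean_ap_at_n(results, n=n)
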