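"""Fast Correlation-Based Filter (FCBF) feature selection.

FCBF ranks discrete features by symmetrical uncertainty (SU) with the class,
keeps those above a relevance threshold delta, and then removes redundant
features by the predominance rule: walking the ranked list, a feature q is
removed if some earlier surviving (predominant) feature p has
SU(p, q) >= SU(q, class).

Expression values are continuous, so features are first discretized by a
binary median split (values strictly above the per-feature median code 1,
ties go low). Entropies use the plug-in estimator in bits with the usual
0*log(0) := 0 convention; SU(X, Y) = 2*I(X;Y)/(H(X)+H(Y)) and is defined
as 0 when H(X)+H(Y) = 0.

``fcbf_select_reference`` is a direct, unoptimized transcription of the
predominance definition kept as an independent oracle for the optimized
``fcbf_select``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DiscretizedMatrix",
    "SUStat",
    "FCBFResult",
    "discretize",
    "symmetrical_uncertainty",
    "fcbf_select",
    "fcbf_select_reference",
]


@dataclass
class DiscretizedMatrix:
    """Small-integer codes per feature x sample plus the split thresholds."""

    feature_ids: list[str]
    sample_ids: list[str]
    codes: np.ndarray
    split_rule: np.ndarray  # per-feature median threshold
    degenerate: np.ndarray = field(default=None)  # constant features

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("codes shape does not match ids")
        if self.degenerate is None:
            self.degenerate = np.array([len(np.unique(row)) < 2 for row in self.codes])


@dataclass
class SUStat:
    """Symmetrical uncertainty with its entropy/MI components (bits)."""

    su: float
    h_x: float
    h_y: float
    mi: float


@dataclass
class FCBFResult:
    """Predominant features in rank order, with removal provenance."""

    selected: list[str]
    su_to_class: dict[str, float]
    removed: dict[str, str]  # removed feature -> predominant feature that removed it
    delta: float

    @property
    def selected_su(self) -> list[tuple[str, float]]:
        return [(f, self.su_to_class[f]) for f in self.selected]


def discretize(matrix: ExpressionMatrix) -> DiscretizedMatrix:
    """Binary median split per feature: code 1 iff value > median."""
    if matrix.n_samples < 2:
        raise ValueError("discretization needs at least 2 samples")
    medians = np.median(matrix.values, axis=1)
    codes = (matrix.values > medians[:, None]).astype(np.int64)
    return DiscretizedMatrix(list(matrix.gene_ids), list(matrix.sample_ids),
                             codes, medians)


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def symmetrical_uncertainty(x: Sequence[int], y: Sequence[int]) -> SUStat:
    """SU(X, Y) = 2 I(X;Y) / (H(X) + H(Y)) from empirical frequencies."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny).astype(float)
    h_x = _entropy(joint.sum(axis=1))
    h_y = _entropy(joint.sum(axis=0))
    h_xy = _entropy(joint.ravel())
    mi = max(h_x + h_y - h_xy, 0.0)
    su = 2.0 * mi / (h_x + h_y) if (h_x + h_y) > 0 else 0.0
    return SUStat(su=su, h_x=h_x, h_y=h_y, mi=mi)


def _entropy_rows(counts: np.ndarray) -> np.ndarray:
    """Row-wise plug-in entropy in bits for a (rows x cells) count table."""
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / totals
        terms = np.where(counts > 0, -p * np.log2(p), 0.0)
    return terms.sum(axis=1)


def _su_to_class_all(disc: DiscretizedMatrix, y: np.ndarray) -> np.ndarray:
    """SU of every feature with a binary class, vectorized for binary codes."""
    codes = disc.codes
    if codes.max() <= 1 and y.max() == 1:
        y1 = y.astype(float)
        n11 = codes @ y1
        n10 = codes @ (1 - y1)
        n01 = (1 - codes) @ y1
        n00 = (1 - codes) @ (1 - y1)
        joint = np.stack([n00, n01, n10, n11], axis=1)
        h_x = _entropy_rows(np.stack([n00 + n01, n10 + n11], axis=1))
        h_y = _entropy_rows(np.array([[float((y == 0).sum()), float((y == 1).sum())]]))[0]
        h_xy = _entropy_rows(joint)
        mi = np.maximum(h_x + h_y - h_xy, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            su = np.where(h_x + h_y > 0, 2.0 * mi / (h_x + h_y), 0.0)
        return su
    return np.array([symmetrical_uncertainty(row, y).su for row in codes])


def _su_ranked_list(disc: DiscretizedMatrix, class_labels: np.ndarray,
                    delta: float) -> list[tuple[str, float]]:
    su = _su_to_class_all(disc, class_labels)
    relevant = [(f, float(s)) for f, s in zip(disc.feature_ids, su) if s >= delta]
    # decreasing SU; ties broken by feature id for platform-stable output
    relevant.sort(key=lambda t: (-t[1], t[0]))
    return relevant


def _check_class(class_labels) -> np.ndarray:
    labels = np.asarray(class_labels)
    _, coded = np.unique(labels, return_inverse=True)
    if coded.max() < 1:
        raise ValueError("class labels must have at least 2 levels")
    return coded


def fcbf_select(disc: DiscretizedMatrix, class_labels, delta: float = 0.25) -> FCBFResult:
    """FCBF selection: relevance threshold then predominance pruning.

    Returns the predominant features in decreasing order of SU with the
    class. An empty result (no feature reaches ``delta``) is returned with a
    warning rather than an error.
    """
    coded = _check_class(class_labels)
    if len(coded) != len(disc.sample_ids):
        raise ValueError("class label length does not match samples")
    relevant = _su_ranked_list(disc, coded, delta)
    if not relevant:
        logger.warning("fcbf_select: no feature reached delta=%.3g", delta)
        return FCBFResult([], {}, {}, delta)

    index = {f: i for i, f in enumerate(disc.feature_ids)}
    order = [f for f, _ in relevant]
    su_to_class = dict(relevant)
    alive = dict.fromkeys(order, True)
    removed: dict[str, str] = {}
    for pos, p in enumerate(order):
        if not alive[p]:
            continue
        p_codes = disc.codes[index[p]]
        for q in order[pos + 1:]:
            if not alive[q]:
                continue
            if symmetrical_uncertainty(p_codes, disc.codes[index[q]]).su >= su_to_class[q]:
                alive[q] = False
                removed[q] = p
    selected = [f for f in order if alive[f]]
    return FCBFResult(selected, {f: su_to_class[f] for f in selected}, removed, delta)


def fcbf_select_reference(disc: DiscretizedMatrix, class_labels,
                          delta: float = 0.25) -> FCBFResult:
    """Unoptimized transcription of the predominance definition (test oracle).

    Repeatedly takes the highest-ranked surviving feature as predominant and
    rescans the whole remaining list, recomputing every pairwise SU from
    scratch.
    """
    coded = _check_class(class_labels)
    relevant = _su_ranked_list(disc, coded, delta)
    if not relevant:
        return FCBFResult([], {}, {}, delta)
    index = {f: i for i, f in enumerate(disc.feature_ids)}
    su_to_class = dict(relevant)
    remaining = [f for f, _ in relevant]
    selected: list[str] = []
    removed: dict[str, str] = {}
    while remaining:
        p = remaining[0]
        selected.append(p)
        survivors = []
        for q in remaining[1:]:
            su_pq = symmetrical_uncertainty(disc.codes[index[p]], disc.codes[index[q]]).su
            if su_pq >= su_to_class[q]:
                removed[q] = p
            else:
                survivors.append(q)
        remaining = survivors
    return FCBFResult(selected, {f: su_to_class[f] for f in selected}, removed, delta)
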