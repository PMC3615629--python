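"""Stage-contrast biomarker selection: mRMR ranking + incremental selection.

Genes are ranked by greedy minimum-redundancy / maximum-relevance (mRMR)
mutual information against a two-class stage contrast (A vs B for early
biomarkers, C vs D for late ones), after ternary discretization of each
gene at mean +/- k_sd standard deviations.  Incremental Feature Selection
(IFS) then evaluates leave-one-out nearest-neighbour accuracy on growing
prefixes of the ranking; the shortest prefix attaining the maximum
accuracy is the optimal biomarker set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .cohort import ExpressionCohort

logger = logging.getLogger(__name__)

_EPS = 1e-12


def discretize(values: np.ndarray, k_sd: float = 1.0) -> np.ndarray:
    """Ternary-discretize expression at mean +/- ``k_sd`` population SDs.

    Works on a single gene vector or on a genes x samples matrix (row-wise).
    State -1 for values strictly below mean - k_sd*SD, +1 strictly above
    mean + k_sd*SD, 0 otherwise (boundary values map to 0).  A zero-SD
    (constant) gene discretizes to all zeros.
    """
    arr = np.asarray(values, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[None, :]
    if arr.shape[1] < 2:
        raise ValueError("need at least 2 samples to discretize")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in expression input")
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)  # population SD (ddof=0)
    n_const = int((sd[:, 0] == 0).sum())
    if n_const:
        logger.info("%d constant gene(s) discretized to all-zero states", n_const)
    out = np.zeros(arr.shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        out[arr < mean - k_sd * sd] = -1
        out[arr > mean + k_sd * sd] = 1
    out[(sd == 0).repeat(arr.shape[1], axis=1)] = 0
    return out[0] if squeeze else out


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (nats) of two discrete vectors."""
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.size == 0:
        raise ValueError("empty input")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    kx, ky = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ky + yi, minlength=kx * ky).reshape(kx, ky) / x.size
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / (px @ py)[nz])))


def _mi_profile(codes: np.ndarray, y: np.ndarray, n_y_states: int) -> np.ndarray:
    """MI (nats) of every row of ternary *codes* (values 0..2) against *y*."""
    n = codes.shape[1]
    joint = np.empty((codes.shape[0], 3, n_y_states))
    for xs in range(3):
        mask = codes == xs
        for ys in range(n_y_states):
            joint[:, xs, ys] = (mask & (y == ys)).sum(axis=1)
    joint /= n
    px = joint.sum(axis=2, keepdims=True)
    py = joint.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (px * py))
    return np.nansum(terms, axis=(1, 2))


def mrmr_rank(
    values: np.ndarray,
    labels: np.ndarray,
    n_top: int | None = None,
    scheme: str = "MIQ",
    k_sd: float = 1.0,
) -> np.ndarray:
    """Greedy mRMR ranking of genes against a two-class label vector.

    Parameters
    ----------
    values
        Genes x samples expression matrix (continuous; discretized here).
    labels
        Per-sample class labels (any two hashable values).
    n_top
        Number of genes to rank; defaults to all.  Values above the gene
        count are truncated with a warning.
    scheme
        ``MIQ`` (relevance / mean redundancy, the default of the canonical
        mRMR program) or ``MID`` (relevance - mean redundancy).
    k_sd
        Discretization width in population SDs.

    Returns gene row indices in selection order.  Ties at every greedy step
    break toward the smaller input index, making the ranking deterministic.
    """
    if scheme not in ("MIQ", "MID"):
        raise ValueError(f"unknown mRMR scheme {scheme!r}")
    values = np.asarray(values, dtype=float)
    n_genes = values.shape[0]
    _, y = np.unique(np.asarray(labels).ravel(), return_inverse=True)
    if y.shape[0] != values.shape[1]:
        raise ValueError("label length does not match sample count")
    n_classes = int(y.max()) + 1
    if n_top is None:
        n_top = n_genes
    if n_top > n_genes:
        logger.warning("n_top=%d exceeds gene count %d; truncating", n_top, n_genes)
        n_top = n_genes

    codes = (discretize(values, k_sd=k_sd) + 1).astype(np.int8)  # states 0..2
    relevance = _mi_profile(codes, y, n_classes)

    order = np.empty(n_top, dtype=int)
    selected = np.zeros(n_genes, dtype=bool)
    order[0] = int(np.argmax(relevance))  # argmax takes the first among ties
    selected[order[0]] = True
    red_sum = np.zeros(n_genes)
    for step in range(1, n_top):
        red_sum += _mi_profile(codes, codes[order[step - 1]], 3)
        mean_red = red_sum / step
        if scheme == "MIQ":
            score = relevance / np.maximum(mean_red, _EPS)
        else:
            score = relevance - mean_red
        score[selected] = -np.inf
        order[step] = int(np.argmax(score))
        selected[order[step]] = True
    return order


def _standardize_rows(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0  # constant gene contributes nothing to distances
    return (values - mean) / sd


def _loocv_from_sqdist(d2: np.ndarray, y: np.ndarray) -> float:
    d2 = d2.copy()
    np.fill_diagonal(d2, np.inf)
    nearest = np.argmin(d2, axis=1)  # first index among ties: deterministic
    return float(np.mean(y[nearest] == y))


def nna_loocv_accuracy(values: np.ndarray, labels: np.ndarray) -> float:
    """Leave-one-out nearest-neighbour accuracy on the given genes.

    Each sample is predicted as the label of its nearest other sample by
    Euclidean distance on per-gene standardized expression; distance ties
    resolve to the smallest sample index.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    _, y = np.unique(np.asarray(labels).ravel(), return_inverse=True)
    if y.shape[0] != values.shape[1]:
        raise ValueError("label length does not match sample count")
    counts = np.bincount(y)
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 samples per class for LOOCV")
    z = _standardize_rows(values)
    sq = (z ** 2).sum(axis=0)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (z.T @ z)
    return _loocv_from_sqdist(np.maximum(d2, 0.0), y)


@dataclass
class IFSCurve:
    """LOOCV accuracy of the top-k ranked genes, k = 1..len(accuracies)."""

    accuracies: list[float]

    @property
    def optimal_k(self) -> int:
        """Smallest prefix length attaining the maximum accuracy (1-based)."""
        acc = np.asarray(self.accuracies)
        return int(np.argmax(acc)) + 1

    @property
    def best_accuracy(self) -> float:
        return float(max(self.accuracies))


@dataclass
class BiomarkerSet:
    """mRMR-ranked genes with the IFS-optimal prefix for one stage contrast."""

    contrast: tuple[str, str]
    ranked_genes: list[str]
    curve: IFSCurve

    @property
    def optimal_genes(self) -> list[str]:
        return self.ranked_genes[: self.curve.optimal_k]

    def __len__(self) -> int:
        return self.curve.optimal_k


def ifs_curve(
    ranked_values: np.ndarray, labels: np.ndarray, max_k: int | None = None
) -> IFSCurve:
    """Evaluate LOOCV nearest-neighbour accuracy on ranking prefixes.

    ``ranked_values`` holds genes as rows, already in mRMR order.  The
    squared-distance matrix is grown one gene at a time, which is exactly
    equivalent to a from-scratch LOOCV at every prefix.
    """
    ranked_values = np.atleast_2d(np.asarray(ranked_values, dtype=float))
    _, y = np.unique(np.asarray(labels).ravel(), return_inverse=True)
    n_ranked, n_samples = ranked_values.shape
    if max_k is None:
        max_k = n_ranked
    if not (1 <= max_k <= n_ranked):
        raise ValueError(f"max_k={max_k} outside [1, {n_ranked}]")
    z = _standardize_rows(ranked_values)
    d2 = np.zeros((n_samples, n_samples))
    accuracies = []
    for k in range(max_k):
        diff = z[k][:, None] - z[k][None, :]
        d2 += diff * diff
        accuracies.append(_loocv_from_sqdist(d2, y))
    return IFSCurve(accuracies)


def ifs_select(
    ranked_genes: list[str],
    values: np.ndarray,
    labels: np.ndarray,
    contrast: tuple[str, str],
    max_k: int | None = None,
) -> BiomarkerSet:
    """Pick the optimal biomarker prefix of an mRMR ranking by IFS."""
    if len(ranked_genes) == 0:
        raise ValueError("empty ranking")
    curve = ifs_curve(values, labels, max_k=max_k)
    return BiomarkerSet(contrast=contrast, ranked_genes=list(ranked_genes), curve=curve)


def select_biomarkers(
    cohort: ExpressionCohort,
    contrast: tuple[str, str],
    scheme: str = "MIQ",
    k_sd: float = 1.0,
    max_k: int | None = None,
    n_top: int | None = None,
) -> BiomarkerSet:
    """Full biomarker selection for one stage contrast (e.g. ("A", "B")).

    mRMR ranks genes on the two-stage sample subset, then IFS evaluates
    nearest-neighbour LOOCV accuracy on ranking prefixes up to ``max_k``
    (default ``min(500, n_genes)``).
    """
    c0, c1 = contrast
    if c0 == c1:
        raise ValueError("contrast stages must differ")
    counts = cohort.stage_counts()
    for stage in contrast:
        if counts.get(stage, 0) < 2:
            raise ValueError(
                f"stage {stage!r} has {counts.get(stage, 0)} sample(s); "
                "biomarker selection needs at least 2 per stage"
            )
    samples = cohort.samples_in(contrast)
    sub = cohort.values.loc[:, samples]
    labels = cohort.stages.loc[samples].to_numpy()
    if max_k is None:
        max_k = min(500, cohort.n_genes)
    if n_top is None:
        n_top = max_k
    n_top = max(n_top, max_k)
    order = mrmr_rank(sub.to_numpy(), labels, n_top=n_top, scheme=scheme, k_sd=k_sd)
    ranked_genes = [sub.index[i] for i in order]
    curve = ifs_curve(sub.to_numpy()[order], labels, max_k=max_k)
    logger.info(
        "contrast %s vs %s: optimal set %d genes, accuracy %.3f",
        c0, c1, curve.optimal_k, curve.best_accuracy,
    )
    return BiomarkerSet(contrast=contrast, ranked_genes=ranked_genes, curve=curve)


class MRMRIFSSelector(SelectorMixin, BaseEstimator):
    """Sklearn-style feature selector wrapping mRMR ranking + IFS.

    Fits on ``X`` of shape (n_samples, n_features) and a two-class ``y``;
    the selected support is the IFS-optimal prefix of the mRMR ranking.
    Composes with sklearn pipelines and model selection.

    Attributes
    ----------
    ranking_ : ndarray of feature indices in mRMR order (length max_k_).
    ifs_accuracies_ : LOOCV accuracy at every prefix length.
    optimal_k_ : size of the selected feature set.
    """

    def __init__(self, scheme: str = "MIQ", k_sd: float = 1.0, max_k: int | None = None):
        self.scheme = scheme
        self.k_sd = k_sd
        self.max_k = max_k

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        classes = np.unique(y)
        if classes.shape[0] != 2:
            raise ValueError(
                f"MRMRIFSSelector requires exactly 2 classes, got {classes.shape[0]}"
            )
        values = np.asarray(X, dtype=float).T  # genes x samples internally
        max_k = self.max_k if self.max_k is not None else min(500, values.shape[0])
        max_k = min(max_k, values.shape[0])
        self.ranking_ = mrmr_rank(
            values, y, n_top=max_k, scheme=self.scheme, k_sd=self.k_sd
        )
        curve = ifs_curve(values[self.ranking_], y, max_k=max_k)
        self.ifs_accuracies_ = np.asarray(curve.accuracies)
        self.optimal_k_ = curve.optimal_k
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_[: self.optimal_k_]] = True
        return mask
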