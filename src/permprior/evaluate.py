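"""Evaluation of edge predictors: AUROC, calibration, Brier decomposition,
the three prediction tasks, and the permuted-feature null baseline.

The central question answered here is "how much of a predictor's edge
prediction performance is attributable to node degree alone?". The edge
prior (see :mod:`permprior.prior`) supplies the degree-only baseline;
:func:`permuted_feature_baseline` measures each feature both on the real
network and on an ensemble of degree-preserving permutations, so that
performance decomposes into a degree-attributable part (the permuted
distribution, bounded by the edge prior) and a degree-independent part
(the excess of the unpermuted performance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .netcore import Network, subsample_edges
from .permute import SwapParams, permutation_ensemble
from .prior import PriorTable, candidate_pairs, edge_prior
from . import features as _features

__all__ = [
    "EvaluationReport",
    "PermutedFeatureBaseline",
    "auroc",
    "calibration_report",
    "run_reconstruction_task",
    "run_holdout_task",
    "run_transfer_task",
    "permuted_feature_baseline",
]


@dataclass
class EvaluationReport:
    """Discrimination and calibration summary for one (scores, labels) task.

    ``brier_calibration`` + ``brier_refinement`` equals the mean squared
    error of the binned mean scores against the labels (the two-component
    decomposition of the Brier score); lower calibration components mean
    better-calibrated probabilities. Calibration fields are NaN when the
    scores are not probabilities (outside [0, 1]).
    """

    auroc: float
    n_pos: int
    n_neg: int
    brier_calibration: float = float("nan")
    brier_refinement: float = float("nan")
    calibration_bins: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "auroc": self.auroc,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "brier_calibration": self.brier_calibration,
            "brier_refinement": self.brier_refinement,
        }
        if self.calibration_bins is not None:
            out["calibration_bins"] = self.calibration_bins.to_dict(orient="list")
        return out


def _validate_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be parallel 1-d sequences")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    return scores, labels.astype(np.int64)


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the Mann–Whitney rank statistic.

    Ties receive midranks, so tied positive–negative pairs count 1/2,
    matching the probabilistic definition P(score+ > score−) + P(=)/2.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both positive and negative examples")
    ranks = rankdata(scores)
    return float(
        (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def calibration_report(
    scores,
    labels,
    n_bins: int = 20,
    binning: str = "auto",
) -> EvaluationReport:
    """Calibration curve and two-component Brier decomposition.

    Scores must be probabilities in [0, 1]. ``binning="unique"`` groups
    by exact score value (appropriate for finite-support predictors such
    as the degree-grouped edge prior); ``"quantile"`` uses ``n_bins``
    equal-count bins; ``"auto"`` (default) uses unique-value bins when
    there are at most ``n_bins`` distinct scores, else quantile bins.

    With bin k holding n_k pairs, mean score f_k and event rate o_k:

    * calibration = Σ_k n_k (f_k − o_k)² / N
    * refinement  = Σ_k n_k o_k (1 − o_k) / N

    and their sum is the mean squared error of the binned scores.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    if scores.size == 0:
        raise ValueError("empty input")
    if scores.min() < 0.0 or scores.max() > 1.0:
        raise ValueError("calibration requires probability scores in [0, 1]")

    if binning == "auto":
        binning = "unique" if len(np.unique(scores)) <= n_bins else "quantile"
    exact_values = None
    if binning == "unique":
        exact_values, inverse = np.unique(scores, return_inverse=True)
        groups = inverse
    elif binning == "quantile":
        order = np.argsort(scores, kind="mergesort")
        groups = np.empty(len(scores), dtype=np.int64)
        for k, chunk in enumerate(np.array_split(order, n_bins)):
            groups[chunk] = k
    else:
        raise ValueError(f"unknown binning {binning!r}")

    n_groups = groups.max() + 1
    counts = np.bincount(groups, minlength=n_groups).astype(float)
    nonempty = counts > 0
    if exact_values is not None:
        # within a unique-value bin all scores are identical; use the value
        # itself so the f - o difference is free of summation round-off
        mean_score = exact_values.astype(float).copy()
    else:
        mean_score = np.bincount(groups, weights=scores, minlength=n_groups)
        mean_score[nonempty] /= counts[nonempty]
    event = np.bincount(groups, weights=labels, minlength=n_groups)
    event[nonempty] /= counts[nonempty]
    counts, mean_score, event = counts[nonempty], mean_score[nonempty], event[nonempty]

    N = float(len(scores))
    cal = float(np.sum(counts * (mean_score - event) ** 2) / N)
    ref = float(np.sum(counts * event * (1.0 - event)) / N)

    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    roc = auroc(scores, labels) if 0 < n_pos < len(labels) else float("nan")
    bins = pd.DataFrame(
        {"mean_score": mean_score, "event_rate": event, "count": counts.astype(int)}
    )
    return EvaluationReport(
        auroc=roc,
        n_pos=n_pos,
        n_neg=n_neg,
        brier_calibration=cal,
        brier_refinement=ref,
        calibration_bins=bins,
    )


# ----------------------------------------------------------------------
# Mapping predictor tables onto a pair universe
# ----------------------------------------------------------------------


def _pack(network: Network, I: np.ndarray, J: np.ndarray) -> np.ndarray:
    return I.astype(np.int64) * network.n_target + J.astype(np.int64)


def _predictor_scores(
    predictor, network: Network, I: np.ndarray, J: np.ndarray
) -> np.ndarray:
    """Scores for the pairs (I, J) from a PriorTable or feature DataFrame."""
    if isinstance(predictor, PriorTable):
        df = predictor.table
        value_col = "prior"
    elif isinstance(predictor, pd.DataFrame):
        df = predictor
        value_col = "prior" if "prior" in df.columns else "score"
        if "feature" in df.columns and df["feature"].nunique() > 1:
            raise ValueError("predictor DataFrame must contain a single feature")
    else:
        raise TypeError("predictor must be a PriorTable or a DataFrame")
    src = df["source"].to_numpy(dtype=np.int64)
    tgt = df["target"].to_numpy(dtype=np.int64)
    if not network.directed and not network.bipartite:
        lo = np.minimum(src, tgt)
        hi = np.maximum(src, tgt)
        src, tgt = lo, hi
    series = pd.Series(
        df[value_col].to_numpy(dtype=float), index=_pack(network, src, tgt)
    )
    series = series[~series.index.duplicated(keep="first")]
    wanted = _pack(network, I, J)
    values = series.reindex(wanted).to_numpy()
    if np.isnan(values).any():
        bad = np.flatnonzero(np.isnan(values))[:10]
        pairs = [(int(I[t]), int(J[t])) for t in bad]
        raise ValueError(
            f"predictor does not cover the candidate pair universe; "
            f"first missing pairs: {pairs}"
        )
    return values


def _labels_for_pairs(
    network: Network, I: np.ndarray, J: np.ndarray, edges=None
) -> np.ndarray:
    edges = network.edges if edges is None else edges
    if not edges:
        return np.zeros(len(I), dtype=np.int64)
    arr = np.array(sorted(edges), dtype=np.int64)
    packed_edges = _pack(network, arr[:, 0], arr[:, 1])
    return np.isin(_pack(network, I, J), packed_edges).astype(np.int64)


def _report(scores: np.ndarray, labels: np.ndarray, n_bins: int) -> EvaluationReport:
    if 0.0 <= scores.min() and scores.max() <= 1.0:
        return calibration_report(scores, labels, n_bins=n_bins)
    roc = auroc(scores, labels)
    n_pos = int(labels.sum())
    return EvaluationReport(auroc=roc, n_pos=n_pos, n_neg=len(labels) - n_pos)


# ----------------------------------------------------------------------
# Prediction tasks
# ----------------------------------------------------------------------


def run_reconstruction_task(
    network: Network, predictor, n_bins: int = 20
) -> EvaluationReport:
    """Task: reconstruct a network from a predictor computed on itself.

    Positives are the network's edges; negatives are all other candidate
    pairs. The predictor must cover the full candidate universe.
    """
    I, J = candidate_pairs(network)
    scores = _predictor_scores(predictor, network, I, J)
    labels = _labels_for_pairs(network, I, J)
    return _report(scores, labels, n_bins)


def run_holdout_task(
    network: Network,
    fraction: float,
    seed: int,
    predictor_fn,
    n_bins: int = 20,
) -> EvaluationReport:
    """Task: predict held-out edges from a uniformly subsampled network.

    A fraction of edges is kept; ``predictor_fn(sampled_network)`` builds
    the predictor from the sampled network only. Pairs present in the
    sampled network are excluded from scoring; positives are the held-out
    edges, negatives the remaining non-edges.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    sampled, heldout = subsample_edges(network, fraction, seed)
    if not heldout:
        raise ValueError("held-out edge set is empty; decrease fraction")
    predictor = predictor_fn(sampled)
    I, J = candidate_pairs(sampled)
    in_sampled = _labels_for_pairs(sampled, I, J).astype(bool)
    I, J = I[~in_sampled], J[~in_sampled]
    scores = _predictor_scores(predictor, sampled, I, J)
    labels = _labels_for_pairs(sampled, I, J, edges=heldout)
    return _report(scores, labels, n_bins)


def run_transfer_task(
    train: Network, test: Network, predictor_fn, n_bins: int = 20
) -> EvaluationReport:
    """Task: predict one network's edges from a predictor built on another.

    The two networks must share an index-aligned node universe (align
    labeled networks through a common NodeLabelMap first). The predictor
    is computed on ``train`` only and evaluated over the candidate
    universe against ``test``'s edges; nodes with no train edges simply
    have degree 0 there, giving them zero prior.
    """
    if (
        train.n_source != test.n_source
        or train.n_target != test.n_target
        or train.bipartite != test.bipartite
        or train.directed != test.directed
    ):
        raise ValueError("train and test must share an index-aligned node universe")
    if train.n_source == 0:
        raise ValueError("empty node universe")
    predictor = predictor_fn(train)
    I, J = candidate_pairs(test)
    scores = _predictor_scores(predictor, test, I, J)
    labels = _labels_for_pairs(test, I, J)
    return _report(scores, labels, n_bins)


# ----------------------------------------------------------------------
# Permuted-feature baseline (degree decomposition)
# ----------------------------------------------------------------------


@dataclass
class PermutedFeatureBaseline:
    """A feature's AUROC on the real network vs on permuted networks.

    ``permuted_aurocs`` is the distribution of AUROCs obtained by
    computing the feature on degree-preserving permutations and scoring
    it against the original network's edges — the degree-attributable
    part of the feature's performance. ``prior_auroc`` is the edge
    prior's AUROC on the same task (the degree-only reference line).
    """

    feature_name: str
    feature_auroc: float
    prior_auroc: float
    permuted_aurocs: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {
            "feature_name": self.feature_name,
            "feature_auroc": self.feature_auroc,
            "prior_auroc": self.prior_auroc,
            "permuted_aurocs": list(map(float, self.permuted_aurocs)),
        }


def _feature_scores(network: Network, pairs: np.ndarray, name: str, **kw) -> np.ndarray:
    df = _features.compute_features(network, pairs, features=(name,), **kw)
    return df["score"].to_numpy()


def permuted_feature_baseline(
    network: Network,
    feature_name: str,
    n_permutations: int = 100,
    params: SwapParams | None = None,
    **feature_kwargs,
) -> PermutedFeatureBaseline:
    """Decompose a feature's reconstruction AUROC into degree and excess.

    The feature is computed on the unpermuted network and on each of
    ``n_permutations`` degree-preserving permutations; every score vector
    is evaluated against the ORIGINAL network's edges over the full
    candidate universe. The edge prior (estimated from the same ensemble
    size) provides the degree-only AUROC for comparison.
    """
    if feature_name not in _features.FEATURE_NAMES:
        raise ValueError(f"unknown feature {feature_name!r}")
    params = params or SwapParams()
    I, J = candidate_pairs(network)
    pairs = np.column_stack([I, J])
    labels = _labels_for_pairs(network, I, J)

    feature_auroc = auroc(
        _feature_scores(network, pairs, feature_name, **feature_kwargs), labels
    )
    prior = edge_prior(network, n_permutations, params)
    prior_auroc = auroc(_predictor_scores(prior, network, I, J), labels)

    permuted_aurocs = np.empty(n_permutations)
    for k, (permuted, _) in enumerate(
        permutation_ensemble(network, n_permutations, params)
    ):
        scores = _feature_scores(permuted, pairs, feature_name, **feature_kwargs)
        permuted_aurocs[k] = auroc(scores, labels)
    return PermutedFeatureBaseline(
        feature_name, feature_auroc, prior_auroc, permuted_aurocs
    )
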