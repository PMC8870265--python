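"""Ensemble template-matching classification of cVEP trials.

A test trial is band-pass decomposed, projected through each sub-band's
ensemble filter matrix (all classes' spatial filters at once), and the
Pearson correlation between the flattened projected trial and each
class's flattened projected template is computed.  The per-band
correlations are combined with the filter-bank weights a_k,

    lambda_i = sum_k a_k * corr(vec(template_ik^T W_k), vec(trial_k^T W_k)),

and the predicted class is the argmax over i (ties broken toward the
lowest class index).  Because the weights form a convex combination of
correlations, every score lies in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_processing import FilterBankSpec, filter_bank
from .spatial_filtering import SpatialFilterSet


@dataclass(frozen=True)
class Decision:
    """Per-class scores and the argmax decision for one trial."""

    scores: np.ndarray
    predicted_class: int
    true_class: int | None = None

    @property
    def correct(self) -> bool | None:
        if self.true_class is None:
            return None
        return self.predicted_class == self.true_class


def projected_templates(model: SpatialFilterSet) -> np.ndarray:
    """Pre-project and center model templates for fast scoring.

    Returns an array of shape (n_subbands, K, n * K) holding, per band,
    each class's flattened projected template minus its mean.
    """
    n_bands, K = model.n_subbands, model.n_classes
    out = np.empty((n_bands, K, model.n_samples * K))
    for k in range(n_bands):
        W = model.ensemble[k]  # m x K
        for i in range(K):
            p = (model.templates[k, i].T @ W).ravel()
            out[k, i] = p - p.mean()
    return out


def _corr_with_rows(v: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Pearson correlation of vector ``v`` with each pre-centered row."""
    vc = v - v.mean()
    num = rows @ vc
    denom = np.linalg.norm(rows, axis=1) * np.linalg.norm(vc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / denom, 0.0)
    return r


def score_subband_trial(
    subband_trial: np.ndarray,
    model: SpatialFilterSet,
    spec: FilterBankSpec,
    true_class: int | None = None,
    _proj_templates: np.ndarray | None = None,
) -> Decision:
    """Score an already filter-bank-decomposed trial.

    ``subband_trial`` has shape (n_subbands, m, n).
    """
    if subband_trial.shape != (
        model.n_subbands,
        model.n_channels,
        model.n_samples,
    ):
        raise ValueError(
            f"trial shape {subband_trial.shape} does not match model "
            f"({model.n_subbands}, {model.n_channels}, {model.n_samples})"
        )
    if len(spec.weights) != model.n_subbands:
        raise ValueError("filter-bank spec and model disagree on sub-band count")
    pt = projected_templates(model) if _proj_templates is None else _proj_templates
    scores = np.zeros(model.n_classes)
    for k in range(model.n_subbands):
        proj = (subband_trial[k].T @ model.ensemble[k]).ravel()
        scores += spec.weights[k] * _corr_with_rows(proj, pt[k])
    predicted = int(np.argmax(scores)) + 1  # argmax returns the first/lowest index on ties
    return Decision(scores=scores, predicted_class=predicted, true_class=true_class)


def score_trial(
    trial: np.ndarray,
    model: SpatialFilterSet,
    spec: FilterBankSpec,
    sampling_rate: float,
    true_class: int | None = None,
) -> Decision:
    """Score a raw (broadband) trial of shape (channels, samples)."""
    trial = np.asarray(trial, dtype=float)
    if trial.shape != (model.n_channels, model.n_samples):
        raise ValueError(
            f"trial shape {trial.shape} does not match model "
            f"({model.n_channels}, {model.n_samples})"
        )
    decomposed = filter_bank(trial, spec, sampling_rate)
    return score_subband_trial(decomposed, model, spec, true_class=true_class)


def block_accuracy(
    block_trials: np.ndarray,
    labels: np.ndarray,
    model: SpatialFilterSet,
    spec: FilterBankSpec,
    sampling_rate: float,
) -> float:
    """Fraction of a block's trials classified correctly.

    ``block_trials`` has shape (n_trials, channels, samples) with one
    trial per target; ``labels`` are the true 1-based classes.
    """
    block_trials = np.asarray(block_trials, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if block_trials.shape[0] != labels.size:
        raise ValueError("one label per trial required")
    if len(set(labels.tolist())) != labels.size:
        raise ValueError("duplicate target labels within a block")
    expected = set(range(1, model.n_classes + 1))
    if labels.size == model.n_classes and set(labels.tolist()) != expected:
        missing = sorted(expected - set(labels.tolist()))
        raise ValueError(f"block is missing targets: {missing}")
    decomposed = filter_bank(block_trials, spec, sampling_rate)  # bands x trials x m x n
    pt = projected_templates(model)
    n_correct = 0
    for j in range(block_trials.shape[0]):
        d = score_subband_trial(
            decomposed[:, j], model, spec, true_class=int(labels[j]), _proj_templates=pt
        )
        n_correct += int(bool(d.correct))
    return n_correct / labels.size
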