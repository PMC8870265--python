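"""CCA-derived spatial filters and ensemble template construction.

For each target class the training trials (channels x samples) are
horizontally concatenated into T_hat, and the class template (the mean
trial) is tiled to the same width into X.  The first canonical
correlation between T_hat and X yields a per-channel weight vector w_i
that projects the multi-channel EEG onto a single virtual channel in
which the class's evoked response is maximally reproducible.  The
per-class filters are concatenated column-wise into the ensemble filter
matrix used by the template-matching classifier; filters and templates
are computed per filter-bank sub-band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .signal_processing import FilterBankSpec, filter_bank

#: Relative ridge added to each auto-covariance: lambda = RIDGE * trace/m.
#: Concatenated short trials at m = 16 channels can be near-singular.
RIDGE = 1e-8


@dataclass(frozen=True)
class CCAResult:
    """First canonical pair of a two-view CCA problem.

    ``weights_x`` / ``weights_y`` are normalized so each projected
    variate has unit variance (up to the ridge term); ``rho`` is the
    first canonical correlation, clipped into [0, 1].
    """

    weights_x: np.ndarray
    weights_y: np.ndarray
    rho: float


def _fix_sign(w: np.ndarray) -> np.ndarray:
    # CCA weights are determined only up to sign; pin the sign so the
    # largest-magnitude entry is positive for bit-exact reproducibility.
    i = int(np.argmax(np.abs(w)))
    return -w if w[i] < 0 else w


def solve_cca(X: np.ndarray, Y: np.ndarray, ridge: float = RIDGE) -> CCAResult:
    """First canonical correlation of row-variable matrices X, Y.

    Parameters
    ----------
    X, Y : ndarray, shape (m1, n) and (m2, n)
        Two views of the same n observations, one variable per row.
        Rows are mean-centered internally.
    ridge : float
        Relative Tikhonov term added to both auto-covariances.

    Notes
    -----
    Solved by Cholesky whitening: with Cxx = X X^T / n etc. (after
    centering), K = Lx^-1 Cxy Ly^-T for Cholesky factors Lx, Ly; the
    singular values of K are the canonical correlations and the
    back-transformed singular vectors the weights.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must be 2-D with a shared sample axis")
    n = X.shape[1]
    if n <= max(X.shape[0], Y.shape[0]):
        raise ValueError("need more samples than variables in either view")
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    if not Xc.any() or not Yc.any():
        raise ValueError("degenerate all-constant input")
    # standardize rows (CCA is invariant to per-variable rescaling; doing it
    # explicitly makes the ridge act on the same problem at any input scale)
    sx = Xc.std(axis=1, keepdims=True)
    sy = Yc.std(axis=1, keepdims=True)
    sx[sx == 0] = 1.0
    sy[sy == 0] = 1.0
    Xc = Xc / sx
    Yc = Yc / sy
    Cxx = Xc @ Xc.T / n
    Cyy = Yc @ Yc.T / n
    Cxy = Xc @ Yc.T / n
    Cxx += ridge * (np.trace(Cxx) / Cxx.shape[0] + 1e-300) * np.eye(Cxx.shape[0])
    Cyy += ridge * (np.trace(Cyy) / Cyy.shape[0] + 1e-300) * np.eye(Cyy.shape[0])
    Lx = linalg.cholesky(Cxx, lower=True)
    Ly = linalg.cholesky(Cyy, lower=True)
    K = linalg.solve_triangular(Lx, Cxy, lower=True)
    K = linalg.solve_triangular(Ly, K.T, lower=True).T
    u, s, vt = linalg.svd(K, full_matrices=False)
    wx = linalg.solve_triangular(Lx.T, u[:, 0], lower=False) / sx[:, 0]
    wy = linalg.solve_triangular(Ly.T, vt[0], lower=False) / sy[:, 0]
    return CCAResult(
        weights_x=_fix_sign(wx),
        weights_y=_fix_sign(wy),
        rho=float(np.clip(s[0], 0.0, 1.0)),
    )


def build_class_filter(trials: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spatial filter and template for one class from its training trials.

    Parameters
    ----------
    trials : ndarray, shape (n_b, m, n)
        The class's training trials (channels x samples each).

    Returns
    -------
    w : ndarray, shape (m,)
        The X-side CCA weight of solve_cca(T_hat, X), rescaled to unit
        Euclidean norm (projection correlations are scale-invariant).
    template : ndarray, shape (m, n)
        The mean trial.
    """
    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 3:
        raise ValueError("trials must have shape (n_trials, channels, samples)")
    n_b = trials.shape[0]
    template = trials.mean(axis=0)
    t_hat = np.concatenate(list(trials), axis=1)  # m x (n_b * n)
    x_tiled = np.tile(template, (1, n_b))
    res = solve_cca(t_hat, x_tiled)
    w = res.weights_x / np.linalg.norm(res.weights_x)
    return _fix_sign(w), template


@dataclass(frozen=True)
class SpatialFilterSet:
    """Per-class filters, ensemble matrix and templates, per sub-band.

    Attributes
    ----------
    ensemble : ndarray, shape (n_subbands, m, K)
        Column i of band k is class i's spatial filter in that band.
    templates : ndarray, shape (n_subbands, K, m, n)
        Per-class mean trials after sub-band filtering.
    """

    ensemble: np.ndarray
    templates: np.ndarray

    def __post_init__(self) -> None:
        if self.ensemble.ndim != 3 or self.templates.ndim != 4:
            raise ValueError("ensemble must be 3-D and templates 4-D")
        if self.ensemble.shape[:2] != (
            self.templates.shape[0],
            self.templates.shape[2],
        ) or self.ensemble.shape[2] != self.templates.shape[1]:
            raise ValueError("ensemble and templates disagree on bands/channels/classes")

    @property
    def n_subbands(self) -> int:
        return self.ensemble.shape[0]

    @property
    def n_classes(self) -> int:
        return self.ensemble.shape[2]

    @property
    def n_channels(self) -> int:
        return self.ensemble.shape[1]

    @property
    def n_samples(self) -> int:
        return self.templates.shape[3]

    def class_filter(self, i: int, k: int = 1) -> np.ndarray:
        """Filter of class i (1-based) in sub-band k (1-based)."""
        return self.ensemble[k - 1, :, i - 1]


def build_filter_set_filtered(subband_trials: dict[int, np.ndarray]) -> SpatialFilterSet:
    """Assemble a SpatialFilterSet from already sub-band-filtered trials.

    Parameters
    ----------
    subband_trials : dict class index (1-based) -> ndarray
        Per class an array of shape (n_subbands, n_trials, m, n).
    """
    classes = sorted(subband_trials)
    if classes != list(range(1, len(classes) + 1)):
        missing = sorted(set(range(1, max(classes) + 1)) - set(classes))
        raise ValueError(f"missing training trials for classes: {missing}")
    first = subband_trials[classes[0]]
    n_bands, _, m, n = first.shape
    filters = np.empty((n_bands, m, len(classes)))
    templates = np.empty((n_bands, len(classes), m, n))
    for i in classes:
        arr = np.asarray(subband_trials[i], dtype=float)
        if arr.shape[0] != n_bands or arr.shape[2:] != (m, n):
            raise ValueError(f"class {i} trial shape mismatch")
        for k in range(n_bands):
            w, tpl = build_class_filter(arr[k])
            filters[k, :, i - 1] = w
            templates[k, i - 1] = tpl
    return SpatialFilterSet(ensemble=filters, templates=templates)


def build_filter_set(
    training: dict[int, np.ndarray],
    spec: FilterBankSpec,
    sampling_rate: float,
) -> SpatialFilterSet:
    """Filter-bank decompose raw training trials and build the model.

    Parameters
    ----------
    training : dict class index (1-based) -> ndarray (n_trials, m, n)
        Raw (broadband) training trials per class.
    spec : FilterBankSpec
    sampling_rate : float
    """
    decomposed = {
        i: filter_bank(np.asarray(trials, dtype=float), spec, sampling_rate)
        for i, trials in training.items()
    }
    return build_filter_set_filtered(decomposed)
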