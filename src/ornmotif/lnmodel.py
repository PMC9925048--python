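"""Linear-nonlinear (LN) receptive-field estimation and filter-space PCA.

The firing rate of an ORN driven by a plume is approximated as
r(t) = g[s(t) * f(t)]: the stimulus convolved with a linear filter f and
passed through a static nonlinearity g.  The filter is estimated by
regularized deconvolution: solve the least-squares problem on the stimulus
convolution matrix, decorrelate with an SVD-regularized inverse stimulus
covariance (components covering 70% of variance kept), low-pass at 10 Hz and
L2-normalize.  The nonlinearity is a 100-bin histogram lookup mapping
filtered-stimulus values to mean observed rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal
from scipy.linalg import toeplitz

from ornmotif.stimuli import StimulusTrace

#: Working grid for LN fitting, seconds; rates are smoothed with a 50 ms
#: Gaussian so a finer grid adds no information.
LN_DT = 0.01
FILTER_SUPPORT_S = 2.0
VAR_KEEP = 0.70
N_BINS = 100
LOWPASS_STOP_HZ = 10.0


@dataclass
class LNModel:
    """Fitted LN cascade: unit-norm filter plus binned nonlinearity."""

    filter: np.ndarray          # (L,) unit L2 norm, delay grid LN_DT
    nl_x: np.ndarray            # bin centers of the filtered stimulus
    nl_y: np.ndarray            # mean firing rate per bin (spikes/s, >= 0)
    dt: float = LN_DT
    train_span: Optional[tuple[float, float]] = None

    @property
    def delays(self) -> np.ndarray:
        return np.arange(len(self.filter)) * self.dt

    @property
    def peak_delay(self) -> float:
        """Delay of the filter maximum, seconds."""
        return float(np.argmax(self.filter) * self.dt)

    def nonlinearity(self, x) -> np.ndarray:
        """Interpolated lookup g(x), clamped at the edges, floored at 0."""
        return np.maximum(np.interp(x, self.nl_x, self.nl_y), 0.0)

    def to_text(self, filter_path, nl_path) -> None:
        np.savetxt(filter_path, np.column_stack([self.delays, self.filter]),
                   header="delay_s weight")
        np.savetxt(nl_path, np.column_stack([self.nl_x, self.nl_y]),
                   header="x_center rate_hz")


def downsample_stimulus(stimulus: StimulusTrace, dt: float = LN_DT) -> np.ndarray:
    """Block-average the stimulus onto the LN working grid."""
    factor = int(round(dt / stimulus.dt))
    if abs(factor * stimulus.dt - dt) > 1e-12:
        raise ValueError("LN grid must be a multiple of the stimulus step")
    s = stimulus.samples
    n = (len(s) // factor) * factor
    return s[:n].reshape(-1, factor).mean(axis=1)


def _convolution_matrix(s: np.ndarray, n_taps: int) -> np.ndarray:
    """Toeplitz matrix X with X @ f = (s * f) truncated causally."""
    col = s
    row = np.zeros(n_taps)
    row[0] = s[0]
    return toeplitz(col, row)


def _lowpass(f: np.ndarray, dt: float) -> np.ndarray:
    """Zero-phase FIR low-pass, passband 8 Hz, stopband 10 Hz."""
    nyq = 0.5 / dt
    numtaps = min(len(f) - 1 if len(f) % 2 == 0 else len(f), 101)
    if numtaps < 9:
        return f
    if numtaps % 2 == 0:
        numtaps -= 1
    taps = signal.firwin(numtaps, (8.0 + LOWPASS_STOP_HZ) / 2 / nyq, window="hamming")
    return signal.filtfilt(taps, [1.0], f, padlen=min(3 * numtaps, len(f) - 1))


def estimate_filter(
    stimulus: np.ndarray,
    rate: np.ndarray,
    dt: float = LN_DT,
    support: float = FILTER_SUPPORT_S,
    var_keep: float = VAR_KEEP,
    lowpass: bool = True,
) -> np.ndarray:
    """Estimate the linear filter by regularized deconvolution.

    ``stimulus`` and ``rate`` are aligned arrays on the LN grid (training
    span only).  Steps: (i) form the causal convolution matrix of the
    stimulus; (ii) solve for the filter by least squares; (iii) decorrelate
    with the SVD-regularized inverse stimulus covariance keeping components
    that account for ``var_keep`` of the variance; (iv) 10 Hz low-pass;
    (v) L2-normalize.
    """
    stimulus = np.asarray(stimulus, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if len(stimulus) != len(rate):
        raise ValueError("stimulus and rate must be aligned")
    if np.ptp(stimulus) == 0:
        raise ValueError("constant stimulus: filter is unidentifiable")
    n_taps = int(round(support / dt))
    if n_taps >= len(stimulus):
        raise ValueError("filter support exceeds the training span")
    X = _convolution_matrix(stimulus - stimulus.mean(), n_taps)
    y = rate - rate.mean()
    # raw deconvolution: correlation-domain solution X^T y, then decorrelation
    # by the regularized inverse of the stimulus covariance C = X^T X
    C = X.T @ X
    xc = X.T @ y
    U, sv, _ = np.linalg.svd(C, hermitian=True)
    frac = np.cumsum(sv) / sv.sum()
    n_keep = int(np.searchsorted(frac, var_keep) + 1)
    # inverse computed exactly on the leading eigenspace covering var_keep of
    # the stimulus variance; the remaining directions are clipped at the
    # boundary eigenvalue instead of amplified (or zeroed), so a white
    # stimulus -- whose spectrum is flat -- is left essentially untouched
    # while correlated-plume noise directions are not blown up
    sv_reg = np.maximum(sv, sv[n_keep - 1])
    f = U @ ((U.T @ xc) / sv_reg)
    if lowpass:
        f = _lowpass(f, dt)
    norm = np.linalg.norm(f)
    if norm == 0:
        raise ValueError("degenerate filter (all-zero)")
    return f / norm


def filtered_stimulus(stimulus: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """Causal convolution of the (mean-centered) stimulus with the filter."""
    s = np.asarray(stimulus, dtype=float)
    full = np.convolve(s - s.mean(), filt)
    return full[:len(s)]


def estimate_nonlinearity(
    stimulus: np.ndarray,
    rate: np.ndarray,
    filt: np.ndarray,
    n_bins: int = N_BINS,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram nonlinearity: per-bin mean filtered value vs mean rate.

    Empty bins are interpolated across (and flagged with a warning).
    Returns (x_centers, y_rates).
    """
    z = filtered_stimulus(stimulus, filt)
    edges = np.linspace(z.min(), z.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(z, edges) - 1, 0, n_bins - 1)
    xs = np.full(n_bins, np.nan)
    ys = np.full(n_bins, np.nan)
    for b in range(n_bins):
        m = which == b
        if m.any():
            xs[b] = z[m].mean()
            ys[b] = rate[m].mean()
    ok = ~np.isnan(xs)
    if not ok.all():
        import warnings
        warnings.warn(f"{int((~ok).sum())} empty nonlinearity bins interpolated")
    centers = 0.5 * (edges[:-1] + edges[1:])
    xs = np.where(ok, xs, centers)
    ys[~ok] = np.interp(centers[~ok], centers[ok], ys[ok])
    return xs, ys


def fit_ln_model(
    stimulus: StimulusTrace,
    rate: np.ndarray,
    train_span: tuple[float, float] = (0.0, 16.0),
    dt: float = LN_DT,
    support: float = FILTER_SUPPORT_S,
    var_keep: float = VAR_KEEP,
) -> LNModel:
    """Fit filter and nonlinearity on a training stretch of the record.

    ``rate`` is the smoothed trial-averaged rate on the LN grid for the full
    record; ``train_span`` (seconds) selects the training stretch.
    """
    s = downsample_stimulus(stimulus, dt)
    n = min(len(s), len(rate))
    s, r = s[:n], np.asarray(rate[:n], dtype=float)
    i0, i1 = int(round(train_span[0] / dt)), int(round(train_span[1] / dt))
    if not (0 <= i0 < i1 <= n):
        raise ValueError("train_span outside the record")
    f = estimate_filter(s[i0:i1], r[i0:i1], dt=dt, support=support, var_keep=var_keep)
    nl_x, nl_y = estimate_nonlinearity(s[i0:i1], r[i0:i1], f)
    return LNModel(filter=f, nl_x=nl_x, nl_y=nl_y, dt=dt, train_span=train_span)


def predict_rate(
    stimulus: StimulusTrace,
    model: LNModel,
    rate: Optional[np.ndarray] = None,
    n_ensemble: int = 8,
    ci: float = 95.0,
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Predict r(t) = g[s * f]; optional CI from shifted training stretches.

    If ``rate`` (the observed rate on the LN grid) is given, an ensemble of
    models is fitted on ``n_ensemble`` shifted 50%-of-record training
    stretches and the pointwise ``ci``% band of their predictions is
    returned as a (2, T) array; otherwise the band is None.
    """
    s = downsample_stimulus(stimulus, model.dt)
    if len(s) < len(model.filter):
        raise ValueError("stimulus shorter than the filter support")
    pred = model.nonlinearity(filtered_stimulus(s, model.filter))
    band = None
    if rate is not None:
        n = min(len(s), len(rate))
        half = n // 2
        starts = np.linspace(0, n - half, n_ensemble, dtype=int)
        preds = []
        for st in starts:
            span = (st * model.dt, (st + half) * model.dt)
            try:
                m = fit_ln_model(stimulus, rate, train_span=span, dt=model.dt,
                                 support=len(model.filter) * model.dt)
            except ValueError:
                continue
            preds.append(m.nonlinearity(filtered_stimulus(s, m.filter)))
        if preds:
            lo = (100.0 - ci) / 2
            band = np.percentile(np.asarray(preds), [lo, 100.0 - lo], axis=0)
    return pred, band


def filter_space_pca(filters: np.ndarray, labels=None):
    """PCA embedding of filter waveforms in the delay dimension.

    ``filters`` is (n_filters, L) on a shared delay grid.  Returns
    (coords (n, 2), components (2, L), explained_variance_ratio (2,)).
    """
    from sklearn.decomposition import PCA

    filters = np.asarray(filters, dtype=float)
    if len(filters) < 3:
        raise ValueError("need at least three filters for a 2-D embedding")
    pca = PCA(n_components=2)
    coords = pca.fit_transform(filters)
    return coords, pca.components_, pca.explained_variance_ratio_
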