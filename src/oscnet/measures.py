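"""Synchrony and directionality measures for multichannel phase data.

The three phase statistics are all built from the pairwise instantaneous
phase difference Δθ_ij(t) = θ_i(t) − θ_j(t):

* mean phase coherence  PC_ij  = |⟨exp(i·Δθ_ij)⟩_t|          ∈ [0, 1]
* directed phase lag index dPLI_ij = ⟨sign(wrap(Δθ_ij))⟩_t   ∈ [−1, 1]
* phase lag index       PLI_ij = |dPLI_ij|                    ∈ [0, 1]

dPLI > 0 means channel i consistently leads channel j.  The phase
difference is wrapped to (−π, π] before taking the sign, so a steady
frequency drift averages to zero rather than saturating.

Also provided: Hilbert-transform phase extraction, zero-phase Butterworth
band-pass filtering, Welch band amplitude, and the two comparison
directionality measures — symbolic transfer entropy (ordinal patterns) and
pairwise Granger causality (ratio of OLS residual variances).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "PhaseMatrix",
    "ConnectivityMatrices",
    "BandSpec",
    "BANDS",
    "instantaneous_phase",
    "mean_phase_coherence",
    "pli",
    "dpli",
    "node_average_dpli",
    "bandpass_filter",
    "band_amplitude",
    "symbolic_transfer_entropy",
    "granger_causality",
    "connectivity_summary",
    "wrap_phase",
]


@dataclass
class BandSpec:
    """A frequency band [lo_hz, hi_hz] in Hz."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.lo_hz < self.hi_hz:
            raise ValueError(f"invalid band {self.name}: ({self.lo_hz}, {self.hi_hz})")


#: the six standard EEG analysis bands
BANDS = {
    "delta": BandSpec("delta", 0.5, 4.0),
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 13.0),
    "beta": BandSpec("beta", 13.0, 25.0),
    "gamma": BandSpec("gamma", 25.0, 55.0),
    "whole": BandSpec("whole", 0.5, 55.0),
}


@dataclass
class PhaseMatrix:
    """Instantaneous phases, channels × samples, in radians."""

    phases: np.ndarray
    fs: float
    source: str = "model_theta"  # or "hilbert"

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if not np.isfinite(self.phases).all():
            raise ValueError("phases contain non-finite values")


@dataclass
class ConnectivityMatrices:
    """Pairwise PC / PLI / dPLI plus per-node mean dPLI."""

    pc: np.ndarray
    pli: np.ndarray
    dpli: np.ndarray
    node_dpli: np.ndarray


def wrap_phase(d: np.ndarray) -> np.ndarray:
    """Wrap angles to (−π, π]."""
    w = np.mod(d, 2.0 * math.pi)
    return np.where(w > math.pi, w - 2.0 * math.pi, w)


def _as_phases(phases: PhaseMatrix | np.ndarray) -> np.ndarray:
    return phases.phases if isinstance(phases, PhaseMatrix) else np.asarray(phases, dtype=float)


def _window_slice(theta: np.ndarray, window: slice | tuple[int, int] | None) -> np.ndarray:
    if window is None:
        return theta
    if isinstance(window, tuple):
        window = slice(*window)
    out = theta[:, window]
    if out.shape[1] == 0:
        raise ValueError("empty analysis window")
    return out


def instantaneous_phase(signals: np.ndarray, fs: float) -> PhaseMatrix:
    """Instantaneous phase of each channel via the analytic signal.

    Channels are de-meaned before the Hilbert transform.  A constant
    channel has no phase and raises.
    """
    X = np.atleast_2d(np.asarray(signals, dtype=float))
    const = np.flatnonzero(X.std(axis=1) == 0)
    if const.size:
        raise ValueError(f"channel(s) {const.tolist()} are constant; phase undefined")
    X = X - X.mean(axis=1, keepdims=True)
    analytic = sps.hilbert(X, axis=1)
    return PhaseMatrix(np.angle(analytic), fs=fs, source="hilbert")


def mean_phase_coherence(
    phases: PhaseMatrix | np.ndarray, window: slice | tuple[int, int] | None = None
) -> np.ndarray:
    """PC matrix: modulus of the time-averaged unit phasor of Δθ.

    1 for a constant phase difference (any offset), ~0 for drifting,
    unlocked phases.  Diagonal is 1 by convention.
    """
    th = _window_slice(_as_phases(phases), window)
    n = th.shape[0]
    out = np.eye(n)
    ph = np.exp(1j * th)
    for i in range(n):
        # |<e^{i(θ_i-θ_j)}>| computed row-block at a time
        m = (ph[i] * np.conj(ph[i + 1 :])).mean(axis=1)
        out[i, i + 1 :] = np.abs(m)
        out[i + 1 :, i] = out[i, i + 1 :]
    return out


def dpli(
    phases: PhaseMatrix | np.ndarray,
    window: slice | tuple[int, int] | None = None,
    tie_tolerance: float = 1e-9,
) -> np.ndarray:
    """Directed phase lag index: time-mean of sign(wrap(θ_i − θ_j)).

    Antisymmetric with zero diagonal; dpli[i, j] > 0 ⇔ i leads j on average.
    Wrapped differences with magnitude at most ``tie_tolerance`` count as
    ties (sign 0): phase differences at that level are below any numerical
    meaning and arise as floating-point residue of exactly-symmetric node
    pairs.
    """
    th = np.ascontiguousarray(_window_slice(_as_phases(phases), window))
    from ._kernels import dpli_counts

    return dpli_counts(th, tie_tolerance)


def pli(
    phases: PhaseMatrix | np.ndarray,
    window: slice | tuple[int, int] | None = None,
    tie_tolerance: float = 1e-9,
) -> np.ndarray:
    """Phase lag index, the magnitude of dPLI (elementwise)."""
    return np.abs(dpli(phases, window, tie_tolerance))


def node_average_dpli(dpli_matrix: np.ndarray) -> np.ndarray:
    """Mean dPLI of each node with respect to all other nodes.

    Negative values mark nodes that on average phase-lag the rest of the
    network (directional sinks); the vector sums to zero by antisymmetry.
    """
    D = np.asarray(dpli_matrix, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least two nodes")
    if not np.allclose(D, -D.T):
        raise ValueError("dPLI matrix must be antisymmetric")
    return D.sum(axis=1) / (n - 1)


def bandpass_filter(signals: np.ndarray, fs: float, band: BandSpec) -> np.ndarray:
    """Zero-phase 5th-order Butterworth band-pass (forward-backward).

    The forward-backward pass cancels the filter's phase response, so
    phase measures downstream see no filter-induced lag; the effective
    magnitude response is the squared single-pass response.
    """
    if band.hi_hz >= fs / 2:
        raise ValueError(f"band {band.name} upper edge {band.hi_hz} Hz >= Nyquist {fs / 2} Hz")
    sos = sps.butter(5, [band.lo_hz, band.hi_hz], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.atleast_2d(np.asarray(signals, dtype=float)), axis=1)


def band_amplitude(
    signals: np.ndarray,
    fs: float,
    band: BandSpec,
    segment_seconds: float = 2.0,
) -> np.ndarray:
    """Per-channel band amplitude from a Welch mean power spectral density.

    Modified periodograms with a Hamming window (2-s segments, 50%
    overlap) are averaged and the PSD is then averaged over the band's
    frequency bins.
    """
    X = np.atleast_2d(np.asarray(signals, dtype=float))
    nperseg = min(int(segment_seconds * fs), X.shape[1])
    f, psd = sps.welch(X, fs=fs, window="hamming", nperseg=nperseg, axis=1)
    mask = (f >= band.lo_hz) & (f <= band.hi_hz)
    if not mask.any():
        raise ValueError(f"band {band.name} contains no FFT bins at fs={fs}")
    return psd[:, mask].mean(axis=1)


# ---------------------------------------------------------------------------
# comparison directionality measures

def _ordinal_symbols(x: np.ndarray, dim: int) -> np.ndarray:
    """Map each length-``dim`` window of ``x`` to its ordinal pattern index
    (Lehmer code, 0 … dim!−1)."""
    w = np.lib.stride_tricks.sliding_window_view(x, dim)
    ranks = np.argsort(np.argsort(w, axis=1, kind="stable"), axis=1, kind="stable")
    code = np.zeros(w.shape[0], dtype=np.int64)
    for pos in range(dim):
        code = code * (dim - pos) + np.sum(ranks[:, pos + 1 :] < ranks[:, [pos]], axis=1)
    return code


def _ste_at(sym_src: np.ndarray, sym_tgt: np.ndarray, n_sym: int, delta: int) -> float:
    """Transfer entropy (bits) on symbol series at prediction time delta."""
    xf = sym_tgt[delta:]
    xp = sym_tgt[: len(sym_tgt) - delta]
    yp = sym_src[: len(sym_src) - delta]
    m = min(len(xf), len(xp), len(yp))
    joint = np.bincount(
        (xf[:m] * n_sym + xp[:m]) * n_sym + yp[:m], minlength=n_sym**3
    ).reshape(n_sym, n_sym, n_sym).astype(float)
    total = joint.sum()
    p_xyz = joint / total
    p_xz = p_xyz.sum(axis=0, keepdims=True)  # (xp, yp)
    p_xy = p_xyz.sum(axis=2, keepdims=True)  # (xf, xp)
    p_x = p_xyz.sum(axis=(0, 2), keepdims=True)  # (xp,)
    with np.errstate(divide="ignore", invalid="ignore"):
        logterm = np.log2(p_xyz * p_x) - np.log2(p_xy * p_xz)
    mask = p_xyz > 0
    return float(np.sum(p_xyz[mask] * logterm[mask]))


def symbolic_transfer_entropy(
    x: np.ndarray,
    y: np.ndarray,
    embedding_dim: int = 3,
    prediction_time: int | None = None,
    max_prediction_time: int = 50,
) -> float:
    """Symbolic transfer entropy from ``x`` (source) to ``y`` (target), in bits.

    Both series are symbolized by ordinal patterns of ``embedding_dim``
    consecutive samples.  When ``prediction_time`` is None the measure is
    scanned over 1 … ``max_prediction_time`` samples and the maximum is
    returned.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n_sym = math.factorial(embedding_dim)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if len(x) < 20 * n_sym + max_prediction_time:
        raise ValueError("series too short for reliable symbolic estimation")
    sx = _ordinal_symbols(x, embedding_dim)
    sy = _ordinal_symbols(y, embedding_dim)
    if prediction_time is not None:
        return _ste_at(sx, sy, n_sym, prediction_time)
    return max(_ste_at(sx, sy, n_sym, d) for d in range(1, max_prediction_time + 1))


def _ar_residual_var(target: np.ndarray, regressors: list[np.ndarray], order: int) -> float:
    T = len(target)
    Y = target[order:]
    cols = [np.ones(T - order)]
    for series in regressors:
        for lag in range(1, order + 1):
            cols.append(series[order - lag : T - lag])
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return float(resid.var())


def granger_causality(x: np.ndarray, y: np.ndarray, order: int = 12) -> tuple[float, float]:
    """Pairwise Granger causality (gc_xy, gc_yx) as log variance ratios.

    gc_xy = ln(var[y | y-lags] / var[y | y-lags, x-lags]) quantifies how
    much the past of x improves the prediction of y; zero when x carries
    no extra information.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if len(x) <= 10 * order:
        raise ValueError("series too short for the requested model order")
    v_y_r = _ar_residual_var(y, [y], order)
    v_y_f = _ar_residual_var(y, [y, x], order)
    v_x_r = _ar_residual_var(x, [x], order)
    v_x_f = _ar_residual_var(x, [x, y], order)
    if min(v_y_f, v_x_f) <= 0:
        raise FloatingPointError("singular regression in Granger fit")
    return math.log(v_y_r / v_y_f), math.log(v_x_r / v_x_f)


def connectivity_summary(
    phases: PhaseMatrix | np.ndarray, window: slice | tuple[int, int] | None = None
) -> ConnectivityMatrices:
    """PC, PLI, dPLI and node-average dPLI in one pass."""
    D = dpli(phases, window)
    return ConnectivityMatrices(
        pc=mean_phase_coherence(phases, window),
        pli=np.abs(D),
        dpli=D,
        node_dpli=node_average_dpli(D),
    )
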