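"""EEG-style functional-network pipeline.

Mirrors the standard analysis applied to multichannel recordings: segment
into 10-s pseudo-stationary epochs, band-pass each epoch, extract Hilbert
phases, compute PLI for all channel pairs, average across epochs, and keep
the top fraction (default 30%) of PLI pairs as the binary functional
network.  Node degree comes from that binary graph; per-node mean dPLI and
Welch band amplitude come from an analysis band (default alpha), epoch by
epoch, then averaged.  Spearman rank correlations relate the three node
properties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .measures import (
    BandSpec,
    BANDS,
    band_amplitude,
    bandpass_filter,
    dpli as _dpli,
    instantaneous_phase,
    node_average_dpli,
    pli as _pli,
)

__all__ = [
    "FunctionalNetwork",
    "NodeSummary",
    "segment_epochs",
    "build_functional_network",
    "summarize_nodes",
    "spearman",
]


@dataclass
class FunctionalNetwork:
    """Binary functional graph from thresholded epoch-mean PLI."""

    adjacency: np.ndarray
    retained_fraction: float
    band: BandSpec
    mean_pli: np.ndarray

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)


@dataclass
class NodeSummary:
    """Per-channel degree / mean dPLI / amplitude with their correlations.

    ``correlations`` maps pair names ("degree_dpli", "degree_amplitude",
    "dpli_amplitude") to (Spearman rho, two-sided p).
    """

    degree: np.ndarray
    mean_dpli: np.ndarray
    amplitude: np.ndarray
    n_epochs: int
    correlations: dict[str, tuple[float, float]]


def segment_epochs(signals: np.ndarray, fs: float, epoch_seconds: float = 10.0) -> list[np.ndarray]:
    """Split channels×samples into non-overlapping epochs; the trailing
    remainder shorter than one epoch is dropped."""
    X = np.atleast_2d(np.asarray(signals, dtype=float))
    step = int(round(epoch_seconds * fs))
    n = X.shape[1] // step
    if n < 1:
        raise ValueError(
            f"recording of {X.shape[1]} samples is shorter than one "
            f"{epoch_seconds}-s epoch at fs={fs}"
        )
    return [X[:, i * step : (i + 1) * step] for i in range(n)]


def _epoch_pli(epoch: np.ndarray, fs: float, band: BandSpec) -> np.ndarray:
    filt = bandpass_filter(epoch, fs, band)
    return _pli(instantaneous_phase(filt, fs))


def threshold_top_fraction(weights: np.ndarray, retained_fraction: float) -> np.ndarray:
    """Binary adjacency keeping the top fraction of upper-triangle weights.

    The quota is ceil(fraction · N(N−1)/2); ties at the cutoff are broken
    deterministically in lexicographic (i, j) order.
    """
    if not 0 < retained_fraction <= 1:
        raise ValueError("retained_fraction must be in (0, 1]")
    W = np.asarray(weights, dtype=float)
    n = W.shape[0]
    iu, ju = np.triu_indices(n, 1)
    quota = math.ceil(retained_fraction * len(iu))
    # sort by weight descending, then (i, j) ascending for reproducible ties
    order = np.lexsort((ju, iu, -W[iu, ju]))
    keep = order[:quota]
    A = np.zeros((n, n), dtype=np.int8)
    A[iu[keep], ju[keep]] = 1
    A[ju[keep], iu[keep]] = 1
    return A


def build_functional_network(
    epochs: list[np.ndarray],
    fs: float,
    band: BandSpec = BANDS["whole"],
    retained_fraction: float = 0.30,
) -> FunctionalNetwork:
    """Epoch-mean PLI graph thresholded to the top ``retained_fraction``."""
    if not epochs:
        raise ValueError("need at least one epoch")
    mean_pli = np.mean([_epoch_pli(ep, fs, band) for ep in epochs], axis=0)
    A = threshold_top_fraction(mean_pli, retained_fraction)
    return FunctionalNetwork(A, retained_fraction, band, mean_pli)


def summarize_nodes(
    epochs: list[np.ndarray],
    fs: float,
    band_for_network: BandSpec = BANDS["whole"],
    band_for_dpli_amp: BandSpec = BANDS["alpha"],
    retained_fraction: float = 0.30,
) -> NodeSummary:
    """Per-node degree, mean dPLI and amplitude plus their correlations.

    Degree comes from the whole-band functional network by default; dPLI
    and amplitude from the alpha band, computed per epoch then averaged —
    the pairing typically reported for wake/anesthesia comparisons.
    """
    fnet = build_functional_network(epochs, fs, band_for_network, retained_fraction)
    dplis = []
    amps = []
    for ep in epochs:
        filt = bandpass_filter(ep, fs, band_for_dpli_amp)
        ph = instantaneous_phase(filt, fs)
        dplis.append(node_average_dpli(_dpli(ph)))
        amps.append(band_amplitude(ep, fs, band_for_dpli_amp))
    mean_dpli = np.mean(dplis, axis=0)
    amplitude = np.mean(amps, axis=0)
    degree = fnet.degrees
    corrs = {
        "degree_dpli": spearman(degree, mean_dpli),
        "degree_amplitude": spearman(degree, amplitude),
        "dpli_amplitude": spearman(mean_dpli, amplitude),
    }
    return NodeSummary(degree, mean_dpli, amplitude, len(epochs), corrs)


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided large-sample p-value.

    Average ranks on ties; raises when either vector has zero variance
    (the correlation is undefined there).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
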