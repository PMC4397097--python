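"""Synthetic brain-like fixtures: posterior-hub networks and two-state
multichannel recordings.

The anatomical cortical network has a scale-free degree distribution with
an exponential cutoff and its hubs concentrated posteriorly (parietal/
occipital), with low-degree nodes frontal.  ``make_brainlike_network``
reproduces those statistics synthetically; "posterior" here is purely a
sign convention on the y coordinate, not anatomy.

``make_two_state_recordings`` then simulates Stuart-Landau dynamics on
that network twice — intact coupling (γ=0, "wake"-like) and degree-
homogenized coupling (γ=1, "anesthesia"-like, emulating preferential hub
disruption) — and emits the real parts of the oscillator states as
channel recordings, decimated to an EEG-like sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .network import (
    GenerationError,
    Network,
    _connect_components,
    _sample_powerlaw_degrees,
    _stub_match,
    build_delay_matrix,
)
from .simulate import SimulationConfig, coupling_from_cycles, simulate_stuart_landau

__all__ = ["BrainLikeFixture", "make_brainlike_network", "make_two_state_recordings"]

_MAX_RESAMPLE = 10_000


@dataclass
class BrainLikeFixture:
    """A network plus wake-like / anesthesia-like recordings and ground truth.

    ``state_recordings`` maps state name → channels×samples array at
    ``fs`` Hz; ``truth`` holds per-node structural degree and an
    anterior/central/posterior group label (y-terciles).
    """

    network: Network
    state_recordings: dict[str, np.ndarray]
    fs: float
    truth: pd.DataFrame


def make_brainlike_network(
    n: int = 78,
    exponent: float = 2.0,
    cutoff_scale: float = 10.0,
    seed: int | np.random.Generator | None = None,
) -> Network:
    """Connected network with P(k) ∝ k^(−exponent)·exp(−k/cutoff_scale)
    degrees and high-degree nodes placed at negative ("posterior") y.

    Coordinates span roughly 120 mm along y; nodes are laid out by degree
    rank (hubs most posterior) with small isotropic jitter so that
    pairwise distances are non-degenerate.
    """
    if n < 20:
        raise ValueError("need at least 20 nodes")
    rng = np.random.default_rng(seed)
    net = None
    for _ in range(_MAX_RESAMPLE):
        degrees = _sample_powerlaw_degrees(n, exponent, rng, cutoff_scale=cutoff_scale)
        A = _stub_match(degrees, rng)
        if A is None:
            continue
        net = Network(_connect_components(A, rng))
        break
    if net is None:
        raise GenerationError(
            f"could not realize a connected brain-like graph (n={n}, "
            f"exponent={exponent}, cutoff_scale={cutoff_scale})"
        )
    # degree-ranked posterior→anterior axis: highest degree at y = −60 mm
    order = np.argsort(-net.degrees, kind="stable")
    y = np.empty(n)
    y[order] = np.linspace(-60.0, 60.0, n)
    coords = np.column_stack(
        [
            rng.normal(0.0, 20.0, size=n),
            y + rng.normal(0.0, 0.5, size=n),
            rng.normal(0.0, 10.0, size=n),
        ]
    )
    return Network(net.adjacency, coordinates=coords)


def make_two_state_recordings(
    net: Network,
    duration_s: float = 300.0,
    fs: float = 500.0,
    seed: int | None = None,
    delay_ms: float = 10.0,
    coupling_strength: float = coupling_from_cycles(1.5),
    burn_in_s: float = 5.0,
    model_fs: float = 1000.0,
) -> BrainLikeFixture:
    """Wake-like (γ=0) and anesthesia-like (γ=1) recordings on ``net``.

    Both states share the same seed, hence the same natural frequencies
    and initial conditions; only the perturbation exponent differs.  The
    simulator runs at ``model_fs`` (1000 Hz) and the Re(z) channel signals
    are decimated to ``fs`` after discarding a ``burn_in_s`` transient.
    """
    if duration_s < 30:
        raise ValueError("duration must be at least 30 s")
    decim = int(round(model_fs / fs))
    if abs(model_fs / fs - decim) > 1e-9:
        raise ValueError("model_fs must be an integer multiple of fs")
    delays = build_delay_matrix(net, "constant", delay_ms / 1000.0)
    n_samples = int(round((duration_s + burn_in_s) * model_fs))
    recordings: dict[str, np.ndarray] = {}
    for state, gamma in (("wake", 0.0), ("anesthesia", 1.0)):
        cfg = SimulationConfig(
            S=coupling_strength,
            gamma=gamma,
            delays=delays,
            fs=model_fs,
            n_samples=n_samples,
            burn_in_fraction=burn_in_s / (duration_s + burn_in_s),
            seed=seed,
        )
        traj = simulate_stuart_landau(net, cfg)
        sig = traj.signals()[:, traj.retained_from :]
        if decim > 1:
            sig = sps.decimate(sig, decim, axis=1, zero_phase=True)
        recordings[state] = sig
    k = net.degrees
    y = net.coordinates[:, 1] if net.coordinates is not None else np.zeros(net.n_nodes)
    terciles = np.quantile(y, [1 / 3, 2 / 3])
    group = np.where(y < terciles[0], "posterior", np.where(y < terciles[1], "central", "anterior"))
    truth = pd.DataFrame({"node": np.arange(net.n_nodes), "degree": k, "group": group})
    return BrainLikeFixture(network=net, state_recordings=recordings, fs=fs, truth=truth)
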