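"""Study protocols: the standard numerical experiments linking network
topology to oscillator dynamics.

Each function runs a complete, self-contained experiment — generate
networks, integrate the oscillators, measure connectivity, correlate with
degree — and returns plain dictionaries of summary numbers.  Both the
test suite and the reproduction script drive these entry points, so the
measured quantities are always produced by the same code path.

Conventions (see also docs/methods.md):

* coupling values quoted in the cycle-unit literature convention are
  converted by 2π (``coupling_from_cycles``); the canonical operating
  point "S = 1.5" is 2π·1.5 ≈ 9.42 in the rad/s equations used here.
* node dPLI and amplitude are averaged over ``n_reps`` independent runs
  (fresh frequencies, initial conditions and noise) before correlating
  with degree, mirroring the run-averaged measurements the pattern was
  established with.
"""

from __future__ import annotations

import numpy as np

from .measures import _ar_residual_var, _ordinal_symbols, _ste_at, dpli, node_average_dpli
from .meanfield import check_amplitude_monotonicity, check_orderings, steady_state_estimates
from .network import Network, build_delay_matrix, generate_random_gilbert, generate_scale_free_catanzaro
from .pipeline import segment_epochs, spearman, summarize_nodes
from .simulate import SimulationConfig, coupling_from_cycles, simulate_kuramoto, simulate_stuart_landau
from .synthetic import make_brainlike_network, make_two_state_recordings

__all__ = [
    "OPERATING_COUPLING",
    "averaged_node_statistics",
    "degree_correlation_ensemble",
    "star_experiment",
    "monotonicity_experiment",
    "measure_identity_checks",
    "two_state_experiment",
    "directionality_concordance",
]

#: 2π × 1.5 — intermediate synchronization (network coherence ≈ 0.3-0.5)
OPERATING_COUPLING = coupling_from_cycles(1.5)


def _child_seeds(seed: int | None, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) >> 1]  # keep below 2**31


def averaged_node_statistics(
    net: Network,
    n_reps: int = 10,
    S: float = OPERATING_COUPLING,
    gamma: float = 0.0,
    delay_ms: float = 10.0,
    model: str = "stuart_landau",
    noise_sd: float = 2.0,
    omega_sd_hz: float = 1.0,
    seed: int | None = None,
) -> dict:
    """Run-averaged node dPLI and amplitude on one network."""
    delays = build_delay_matrix(net, "constant", delay_ms / 1000.0)
    seeds = _child_seeds(seed, n_reps)
    nds, amps = [], []
    for s in seeds:
        cfg = SimulationConfig(
            S=S, gamma=gamma, delays=delays, seed=s, model=model,
            noise_sd=noise_sd, omega_sd_hz=omega_sd_hz,
        )
        traj = (
            simulate_kuramoto(net, cfg) if model == "kuramoto" else simulate_stuart_landau(net, cfg)
        )
        nds.append(node_average_dpli(dpli(traj.theta, (traj.retained_from, None))))
        amps.append(traj.r_retained.mean(axis=1))
    return {"node_dpli": np.mean(nds, axis=0), "amplitude": np.mean(amps, axis=0)}


def degree_correlation_ensemble(
    kind: str = "scale_free",
    n_networks: int = 20,
    n_reps: int = 10,
    n_nodes: int = 78,
    S: float = OPERATING_COUPLING,
    gamma: float = 0.0,
    model: str = "stuart_landau",
    delay_ms: float = 10.0,
    seed: int | None = None,
) -> dict:
    """Spearman(degree, dPLI) and Spearman(degree, amplitude) over an
    ensemble of freshly generated networks.

    Returns per-network correlation arrays plus their means and the
    fraction of networks with the hub-lag sign (dPLI negative, amplitude
    positive).
    """
    seeds = _child_seeds(seed, 2 * n_networks)
    rho_dpli, rho_amp = [], []
    for i in range(n_networks):
        if kind == "scale_free":
            net = generate_scale_free_catanzaro(n_nodes, 2.2, seed=seeds[2 * i])
        elif kind == "random":
            net = generate_random_gilbert(n_nodes, 0.1, seed=seeds[2 * i])
        else:
            raise ValueError(f"unknown ensemble kind {kind!r}")
        stats_i = averaged_node_statistics(
            net, n_reps=n_reps, S=S, gamma=gamma, model=model,
            delay_ms=delay_ms, seed=seeds[2 * i + 1],
        )
        rho_dpli.append(spearman(net.degrees, stats_i["node_dpli"])[0])
        if model == "stuart_landau":
            rho_amp.append(spearman(net.degrees, stats_i["amplitude"])[0])
    rho_dpli = np.asarray(rho_dpli)
    out = {
        "rho_dpli": rho_dpli,
        "mean_rho_dpli": float(rho_dpli.mean()),
        "frac_dpli_negative": float((rho_dpli < 0).mean()),
    }
    if rho_amp:
        rho_amp = np.asarray(rho_amp)
        out.update(
            rho_amp=rho_amp,
            mean_rho_amp=float(rho_amp.mean()),
            frac_amp_positive=float((rho_amp > 0).mean()),
        )
    return out


def star_experiment(
    n_leaves: int = 10,
    S: float = OPERATING_COUPLING,
    delay_ms: float = 10.0,
    n_samples: int = 30_000,
    seed: int = 42,
) -> dict:
    """Deterministic star-graph run: identical 10 Hz oscillators, no noise.

    The hub receives every leaf's input; the mean-field prediction is that
    it oscillates with the largest amplitude and phase-lags all leaves
    (node dPLI = −1 against each leaf)."""
    n = n_leaves + 1
    A = np.zeros((n, n), dtype=int)
    A[0, 1:] = 1
    A[1:, 0] = 1
    net = Network(A)
    delays = build_delay_matrix(net, "constant", delay_ms / 1000.0)
    cfg = SimulationConfig(
        S=S, delays=delays, seed=seed, noise_sd=0.0, omega_sd_hz=0.0, n_samples=n_samples
    )
    traj = simulate_stuart_landau(net, cfg)
    r_star = traj.r_retained.mean(axis=1)
    nd = node_average_dpli(dpli(traj.theta, (traj.retained_from, None)))
    return {
        "center_amplitude": float(r_star[0]),
        "max_leaf_amplitude": float(r_star[1:].max()),
        "center_node_dpli": float(nd[0]),
        "min_leaf_node_dpli": float(nd[1:].min()),
        "center_has_largest_amplitude": bool(np.all(r_star[0] > r_star[1:])),
        "all_leaves_lead": bool(np.all(nd[1:] > 0)),
    }


def monotonicity_experiment(
    n_networks: int = 8,
    n_reps: int = 3,
    S: float = OPERATING_COUPLING,
    delay_ms: float = 10.0,
    seed: int | None = None,
) -> dict:
    """Noise-free replicates: monotonicity of (K·R̃)² in (r*)² and the
    pairwise amplitude ordering for degree-distinct pairs."""
    import warnings as _warnings

    seeds = _child_seeds(seed, 2 * n_networks)
    rho_groups, rho_raws, fracs = [], [], []
    for i in range(n_networks):
        net = generate_scale_free_catanzaro(78, 2.2, seed=seeds[2 * i])
        delays = build_delay_matrix(net, "constant", delay_ms / 1000.0)
        rep_seeds = _child_seeds(seeds[2 * i + 1], n_reps)
        r_stars, R_tildes = [], []
        for s in rep_seeds:
            cfg = SimulationConfig(S=S, delays=delays, seed=s, noise_sd=0.0)
            traj = simulate_stuart_landau(net, cfg)
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", UserWarning)
                st = steady_state_estimates(traj, net)
            r_stars.append(st.r_star)
            R_tildes.append(st.R_tilde)
        st.r_star = np.mean(r_stars, axis=0)
        st.R_tilde = float(np.mean(R_tildes))
        report = check_amplitude_monotonicity(st)
        rho_groups.append(report["rho_group"])
        rho_raws.append(report["rho"])
        ordering = check_orderings(net, st)
        fracs.append(ordering["frac_amplitude_ordering"])
    return {
        "rho_group": np.asarray(rho_groups),
        "rho_raw": np.asarray(rho_raws),
        "frac_amplitude_ordering": np.asarray(fracs),
        "min_rho_group": float(np.min(rho_groups)),
        "min_frac_amplitude_ordering": float(np.min(fracs)),
    }


def measure_identity_checks(seed: int | None = None) -> dict:
    """Exact algebraic identities of the phase measures, evaluated on a
    noisy run plus an uncoupled heterogeneous run for the S=0 null."""
    from .measures import mean_phase_coherence, pli

    net = generate_scale_free_catanzaro(30, 2.2, seed=seed)
    delays = build_delay_matrix(net, "constant", 0.010)
    seeds = _child_seeds(seed, 2)
    cfg = SimulationConfig(S=OPERATING_COUPLING, delays=delays, seed=seeds[0], n_samples=4000)
    traj = simulate_stuart_landau(net, cfg)
    window = (traj.retained_from, None)
    D = dpli(traj.theta, window)
    P = pli(traj.theta, window)
    C = mean_phase_coherence(traj.theta, window)
    # S=0 null: evenly separated frequencies so every beat completes many
    # cycles inside the retained window
    n0 = 12
    A = np.zeros((n0, n0), dtype=int)
    A[0, 1:] = 1
    A[1:, 0] = 1
    null_net = Network(A)
    cfg0 = SimulationConfig(
        S=0.0, noise_sd=0.0, seed=seeds[1], n_samples=60_000,
        omegas=2 * np.pi * np.linspace(8.0, 12.0, n0),
    )
    traj0 = simulate_stuart_landau(null_net, cfg0)
    D0 = dpli(traj0.theta, (traj0.retained_from, None))
    return {
        "max_pli_vs_absdpli_error": float(np.max(np.abs(P - np.abs(D)))),
        "max_antisymmetry_error": float(np.max(np.abs(D + D.T))),
        "pc_within_bounds": bool(np.all((C >= 0) & (C <= 1))),
        "dpli_within_bounds": bool(np.all((D >= -1) & (D <= 1))),
        "max_uncoupled_abs_dpli": float(np.max(np.abs(D0))),
    }


def two_state_experiment(
    n_seeds: int = 20,
    duration_s: float = 120.0,
    fs: float = 500.0,
    seed: int | None = None,
) -> dict:
    """Wake-like vs anesthesia-like recordings through the functional
    pipeline: Spearman(structural degree, alpha mean dPLI) per state."""
    seeds = _child_seeds(seed, n_seeds)
    wake, anesthesia = [], []
    for s in seeds:
        net = make_brainlike_network(78, seed=s)
        fix = make_two_state_recordings(net, duration_s=duration_s, fs=fs, seed=s)
        for state, store in (("wake", wake), ("anesthesia", anesthesia)):
            summary = summarize_nodes(segment_epochs(fix.state_recordings[state], fs, 10.0), fs)
            store.append(spearman(net.degrees, summary.mean_dpli)[0])
    wake = np.asarray(wake)
    anesthesia = np.asarray(anesthesia)
    return {
        "wake_rho": wake,
        "anesthesia_rho": anesthesia,
        "mean_wake_rho": float(wake.mean()),
        "mean_anesthesia_rho": float(anesthesia.mean()),
        "frac_wake_negative": float((wake < 0).mean()),
        "frac_attenuated": float((np.abs(anesthesia) < np.abs(wake)).mean()),
    }


def _pairwise_gc_flows(signals: np.ndarray, order: int = 12) -> np.ndarray:
    """Directed Granger-causality matrix M[k, j] = gc(k → j)."""
    n, _ = signals.shape
    x = signals - signals.mean(axis=1, keepdims=True)
    restricted = np.array([_ar_residual_var(x[j], [x[j]], order) for j in range(n)])
    M = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            if j == k:
                continue
            full = _ar_residual_var(x[j], [x[j], x[k]], order)
            M[k, j] = np.log(restricted[j] / full)
    return M


def _pairwise_ste_flows(
    signals: np.ndarray, embedding_dim: int = 3, max_prediction_time: int = 50
) -> np.ndarray:
    """Directed symbolic-transfer-entropy matrix M[a, b] = STE(a → b),
    with the prediction time scanned per pair for the maximal value."""
    import math

    n, _ = signals.shape
    n_sym = math.factorial(embedding_dim)
    symbols = [_ordinal_symbols(signals[j], embedding_dim) for j in range(n)]
    M = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            M[a, b] = max(
                _ste_at(symbols[a], symbols[b], n_sym, d)
                for d in range(1, max_prediction_time + 1)
            )
    return M


def directionality_concordance(
    seed: int | None = None,
    n_nodes: int = 78,
    S: float = OPERATING_COUPLING,
    max_prediction_time: int = 50,
) -> dict:
    """Do dPLI, Granger causality and symbolic transfer entropy agree on
    who receives?  One scale-free run; per-node inflow is the mean of the
    directed measure over all partners (dPLI inflow is the negated node
    dPLI, since lagging = receiving).  Net-inflow variants (inflow minus
    outflow) are reported alongside: netting subtracts the hubs' equally
    elevated outflow and flips the sign of their ranking, so raw and net
    conventions disagree on these data."""
    seeds = _child_seeds(seed, 2)
    net = generate_scale_free_catanzaro(n_nodes, 2.2, seed=seeds[0])
    delays = build_delay_matrix(net, "constant", 0.010)
    cfg = SimulationConfig(S=S, delays=delays, seed=seeds[1])
    traj = simulate_stuart_landau(net, cfg)
    window = (traj.retained_from, None)
    dpli_inflow = -node_average_dpli(dpli(traj.theta, window))
    signals = traj.signals()[:, traj.retained_from :]
    n = net.n_nodes
    G = _pairwise_gc_flows(signals)
    T = _pairwise_ste_flows(signals, max_prediction_time=max_prediction_time)
    out: dict = {"degree_dpli_inflow_rho": spearman(net.degrees, dpli_inflow)[0]}
    for tag, M in (("gc", G), ("ste", T)):
        out[f"{tag}_inflow"] = M.sum(axis=0) / (n - 1)
        out[f"{tag}_net_inflow"] = (M.sum(axis=0) - M.sum(axis=1)) / (n - 1)
    rhos = {
        "rho_dpli_gc": spearman(dpli_inflow, out["gc_inflow"])[0],
        "rho_dpli_ste": spearman(dpli_inflow, out["ste_inflow"])[0],
        "rho_gc_ste": spearman(out["gc_inflow"], out["ste_inflow"])[0],
    }
    out.update(rhos)
    out["min_rho"] = float(min(rhos.values()))
    out["rho_dpli_gc_net"] = spearman(dpli_inflow, out["gc_net_inflow"])[0]
    out["rho_dpli_ste_net"] = spearman(dpli_inflow, out["ste_net_inflow"])[0]
    return out
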