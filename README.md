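# oscnet

Delay-coupled oscillator networks and phase-directionality analysis for
large-scale brain-network modelling.

## The problem

In cortical networks, which regions drive and which are driven?  A
recurring empirical pattern is that highly connected regions (hubs,
concentrated in posterior-parietal cortex) *receive* — they phase-lag the
rest of the network — while sparsely connected frontal regions lead, and
that anesthesia, which preferentially disrupts hub connectivity, erases
this front-to-back directionality.  `oscnet` implements the
oscillator-network machinery to study this mechanism end to end: it
simulates delay-coupled Stuart-Landau (amplitude + phase) and Kuramoto
(phase-only) oscillators on arbitrary undirected graphs, measures
directionality with the directed phase lag index, runs the same
functional-network pipeline used for EEG, and numerically verifies the
mean-field predictions linking node degree k_j, steady amplitude r*_j and
phase lag.

The model per node j:

    ṙ_j = (λ − r_j²) r_j + (S/g_j^γ) Σ_k K_jk r_k(t−τ_jk) cos(θ_k(t−τ_jk) − θ_j)
    θ̇_j = ω_j            + (S/g_j^γ) Σ_k K_jk (r_k(t−τ_jk)/r_j) sin(θ_k(t−τ_jk) − θ_j)

with adjacency K, coupling S, conduction delays τ, alpha-band natural
frequencies ω_j ~ 2π·N(10 Hz, 1 Hz), and a perturbation exponent γ (γ=0
intact, γ=1 degree-homogenized "hub-disrupted" coupling).  Directionality
between nodes i, j is the directed phase lag index

    dPLI_ij = ⟨ sign(wrap(θ_i − θ_j)) ⟩_t  ∈ [−1, 1],

positive when i leads; PLI = |dPLI|; a node's mean dPLI against all
others marks it as a source (>0) or sink (<0).  The mean-field analysis
predicts that for k_a > k_b: r*_a > r*_b and node a phase-lags node b —
hubs are high-amplitude directional sinks — and that degree-normalized
coupling (γ=1) neutralizes the dPLI pattern.

See `docs/methods.md` for integration details, units (note: coupling
values quoted in the cycle-unit literature convention convert by 2π —
`coupling_from_cycles`), and known limitations.

## Worked example

```python
import oscnet as on

net = on.generate_scale_free_catanzaro(78, exponent=2.2, seed=1)
delays = on.build_delay_matrix(net, "constant", 0.010)        # 10 ms
cfg = on.SimulationConfig(S=on.coupling_from_cycles(1.5),     # ≈ 9.42
                          delays=delays, seed=2)
traj = on.simulate_stuart_landau(net, cfg)                    # 10 s @ 1 kHz

node_dpli = on.node_average_dpli(on.dpli(traj.theta, (traj.retained_from, None)))
amplitude = traj.r_retained.mean(axis=1)
print("degree vs dPLI     rho = %.3f" % on.spearman(net.degrees, node_dpli)[0])
print("degree vs amplitude rho = %.3f" % on.spearman(net.degrees, amplitude)[0])
```

Output:

```
degree vs dPLI     rho = -0.261
degree vs amplitude rho = 0.799
```

A single noisy run already shows the pattern: higher-degree nodes lag
(negative correlation) and oscillate with larger amplitude.  Averaging
node dPLI/amplitude over ~10 runs per network sharpens this to
ρ ≈ −0.5 / +0.9 (see `oscnet.experiments.degree_correlation_ensemble`);
with γ=1 the dPLI correlation collapses toward zero.

The synthetic two-state fixture and EEG-style pipeline:

```python
net = on.make_brainlike_network(78, seed=7)            # posterior hubs
fix = on.make_two_state_recordings(net, duration_s=120, seed=7)
epochs = on.segment_epochs(fix.state_recordings["wake"], fix.fs, 10.0)
summary = on.summarize_nodes(epochs, fix.fs)           # whole-band net, alpha dPLI
print(summary.correlations["degree_dpli"])
```

A command-line interface mirrors the library:
`oscnet net scalefree --n 78 --seed 1 -o net.csv`,
`oscnet simulate --net net.csv --s 9.42 --seed 2 -o traj.h5`,
`oscnet measure --traj traj.h5 -o conn.csv`,
`oscnet pipeline`, `oscnet verify`, `oscnet fixture` — see `--help`.

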