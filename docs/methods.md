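# Methods

## Model

Each node j of an undirected, unweighted graph K (adjacency K_jk ∈ {0,1},
degree g_j) carries a Stuart-Landau oscillator — the normal form of the
Hopf bifurcation — with complex state z_j = r_j·e^{iθ_j}:

    ṙ_j = (λ − r_j²)·r_j + (S/g_j^γ) Σ_k K_jk · r_k(t−τ_jk)·cos(θ_k(t−τ_jk) − θ_j(t))
    θ̇_j = ω_j           + (S/g_j^γ) Σ_k K_jk · (r_k(t−τ_jk)/r_j(t))·sin(θ_k(t−τ_jk) − θ_j(t))

plus independent additive Gaussian white noise on each real equation.
Uncoupled, each node settles on the limit cycle r* = √λ.  Pinning all
amplitudes equal reduces the phase equation to the delay-coupled Kuramoto
model, which the package also integrates directly (r ≡ 1).

The perturbation exponent γ divides every node's coupling by g^γ.  γ=0 is
the intact network; γ=1 normalizes each node's input by its degree, which
homogenizes the effective coupling and models preferential disruption of
hub connectivity (the anesthesia-like state); γ>1 inverts the
hub–periphery relation.

The coupling term in both equations uses the delayed amplitude
r_k(t−τ_jk), the faithful separation of z_k(t−τ_jk) into polar parts.

## Parameters and units

| parameter | default | meaning |
|---|---|---|
| λ | 2 | amplitude parameter, identical across nodes; r*=√2 uncoupled |
| ω_j | 2π·N(10, 1) rad/s | natural frequencies, alpha-band |
| S | — | coupling strength in the rad/s equations |
| γ | 0 | perturbation exponent |
| τ_jk | 10 ms constant, or distance/speed | conduction delays |
| noise sd | 2 | per-equation white-noise intensity (Euler–Maruyama, √dt-scaled) |
| fs, T | 1000 Hz, 10 000 samples | output grid; the first half is burn-in |

**Coupling units.** Much of the large-scale oscillator-network literature
writes the phase equation with natural frequencies in cycles per second
(ν = 10, not ω = 2π·10).  A coupling value quoted in that convention is a
factor 2π smaller than the equivalent value in the rad/s equations above.
We verified this on the observable that defines the canonical operating
point: a 78-node scale-free alpha network is quoted as reaching network
coherence ≈ 0.5 — "in between the extremes" — at S = 1.5.  In the rad/s
equations, S = 1.5 gives coherence ≈ 0.15 and no hub-lag pattern (the
run-averaged degree–dPLI correlation is even slightly positive), whereas
S = 2π·1.5 ≈ 9.42 reproduces coherence 0.3–0.5 under noise together with
the expected degree–amplitude (ρ ≈ +0.9) and degree–dPLI (ρ ≈ −0.5)
correlations.  `oscnet.simulate.coupling_from_cycles` performs the
conversion, and every experiment in `oscnet.experiments` uses the
converted operating point.  All coupling values printed by the package
are in rad/s units.

## Integration

Stochastic Euler (Euler–Maruyama) at dt = 1/fs = 1 ms, with an optional
integer substep factor for convergence checks (the star-graph orderings
are bit-for-bit stable between dt and dt/10, and the ensemble
correlations agree to three decimals between dt and dt/5).  Delays are
rounded to the nearest integer step and read from the full trajectory
history; before t = 0 the initial state is held constant.  Initial
conditions are r_j(0) = √λ (the uncoupled limit cycle) and θ_j(0) ~
U(−π, π] i.i.d., so any directionality must emerge from topology.  The
amplitude is floored at 0 if noise drives it negative, and the r_k/r_j
ratio is guarded at 10⁻⁸.  Noise increments have standard deviation
noise_sd·√dt per step; the noise streams are pre-drawn with numpy's
Generator so results are bit-reproducible for a given seed regardless of
the (numba) kernel backend.

## Connectivity measures

With Δθ_ij(t) = θ_i(t) − θ_j(t) wrapped to (−π, π]:

* PC_ij = |⟨e^{iΔθ}⟩_t| — mean phase coherence, 1 when locked at any lag;
* dPLI_ij = ⟨sign(Δθ)⟩_t ∈ [−1, 1] — positive when i consistently leads;
* PLI_ij = |dPLI_ij| — consistent nonzero lag, robust to zero-lag mixing.

Wrapping before the sign is essential: unwrapped differences under
frequency drift would saturate the sign.  sign(0) = 0, and wrapped
differences below a tie tolerance (default 10⁻⁹ rad) also count as zero:
on exactly symmetric node pairs (e.g. two leaves of a noise-free star)
the true phase difference is zero and the float residue (~10⁻¹²) would
otherwise produce a spurious ±1.  The tolerance is far below any
physically meaningful phase and leaves noisy data untouched.

Model trajectories are measured on θ directly; the functional pipeline
always goes through band-pass filtering (5th-order Butterworth, applied
forward-backward so the filter adds no phase lag) and the Hilbert
analytic-signal phase.  Band amplitude is the mean Welch power spectral
density over the band (Hamming window, 2-s segments, 50% overlap).
Per-node dPLI is the mean of a node's dPLI against all other nodes; by
antisymmetry the node values sum to zero, and negative values mark
directional sinks.

The comparison measures are symbolic transfer entropy (ordinal patterns
of 3 consecutive samples; prediction time scanned over 1–50 samples for
the maximum) and pairwise Granger causality (OLS, order 12, log ratio of
restricted to full residual variance, no small-sample correction).

## Functional pipeline

Recordings (channels × samples) are cut into non-overlapping 10-s
epochs.  Per epoch and band: filter → Hilbert phase → PLI; the epoch-mean
PLI matrix is thresholded to its top 30% of pairs (quota ceil(0.3·N(N−1)/2),
ties broken lexicographically) to give a binary functional network and
its degrees.  Node dPLI and band amplitude are computed per epoch in the
analysis band (default alpha) and averaged.  Degree is taken from the
whole-band (0.5–55 Hz) network by default.  Correlations are Spearman
with the large-sample two-sided p.

## Mean-field checks

From the retained window: r*_j is the time-mean amplitude; the order
parameter R̃, Φ is the time-averaged magnitude/argument of (1/N)·Σ z_j(t)
(the 1/N normalization makes R̃ comparable across N); ϕ*_j is the
circular mean of θ_j − Φ(t).  The predicted monotone relation between
(K_j·R̃)² and (r*_j)², with K_j = k_j·S, is reported three ways: raw
Spearman over nodes, Spearman over degree groups (distinct K vs
within-group mean), and the R² of an isotonic fit.  The group-level rho
is the primary pass statistic: with ~43 tied degree-1 nodes out of 78 the
raw node-level Spearman is capped near 0.87–0.91 even when the relation
is perfectly monotone (the cap is computable by correlating the degree
vector against a perfectly degree-sorted partner), so a raw-rho threshold
of 0.9 would test the tie structure, not the science.  Phase orderings
are tallied over all degree-distinct pairs, restricted to nodes on the
principal branch (|ϕ* + β| < π/2, with β the common delay in phase units)
where the underlying tangent relation is monotone.

## Synthetic data

`make_brainlike_network` draws degrees from P(k) ∝ k^(−exponent)·e^(−k/κ)
(defaults: exponent 2, κ = 10, matching a scale-free distribution with
exponential cutoff), stub-matches them, and lays nodes along a 120-mm
"posterior–anterior" y-axis by degree rank — hubs posterior, with small
jitter.  "Posterior" is purely this 1-D sign convention, not anatomy.
`make_two_state_recordings` integrates the Stuart-Landau model twice with
a shared seed — γ=0 (wake-like) and γ=1 (anesthesia-like) — and emits
Re(z_j) decimated from 1000 Hz to the EEG-like 500 Hz.  What the fixture
does **not** emulate: volume conduction / lead fields, referencing,
artifacts, 1/f background, or non-stationary state transitions.  Passing
pipeline tests on it therefore demonstrates the topology→directionality
mechanism, not EEG realism.

**Degree-sequence connectivity.**  With minimum degree 1 and slope −2.2
the mean degree is ≈1.6 < 2, so most drawn sequences admit *no* connected
graph (connectivity needs at least n−1 edges).  The generator therefore
redraws the sequence until Σk ≥ 2(n−1) — the conditioning that demanding
connected realizations implies — and merges the remaining components
with degree-preserving double-edge swaps anchored on a non-bridge edge
(each swap reduces the component count by exactly one and cannot create
self-loops or multi-edges).  For extremely steep exponents, where even
that conditioning is unsatisfiable, the sequence is used as drawn and the
minimal number of bridging edges is added instead.

## Problem sizes

The reference analyses average ≥1000 runs per condition; this package's
experiments use 12–20 networks × 8–10 runs per ensemble, 120-s two-state
recordings (from the supported 60–300 s range), and single runs for the
directionality-measure comparison.  Node dPLI and amplitude are averaged
over the per-network runs before correlating with degree: a single run's
dPLI is dominated by the random natural-frequency draw (fast nodes lead),
and the degree pattern is a run-averaged property.

## Known limitations

* With γ = 1 on *sparse* graphs the degree–amplitude correlation does not
  vanish but turns negative (≈ −0.6): a homogenized hub's amplitude input
  is the mean coherence of its many mutually less-coherent neighbours.
  On dense graphs (mean degree ≳ 13) the effect shrinks toward zero,
  matching the null reported on dense anatomical networks.
* The anesthesia-like state retains a small systematic positive
  degree–dPLI correlation (≈ +0.1), so per-seed attenuation of the wake
  pattern holds in ~75–90% of seeds rather than ≥95%, independent of
  recording length.
* Granger-causality inflow on these oscillatory signals is confounded by
  node amplitude: hubs both receive and emit elevated GC/STE, so raw
  inflow tracks dPLI inflow positively (ρ ≈ 0.15–0.6) while net inflow
  (inflow − outflow) anti-correlates with degree.  Conclusions that
  depend on a specific inflow convention should be drawn with care.
* Functional degree from top-30% PLI networks correlates only weakly
  (ρ ≈ 0.1–0.3) with structural degree on sparse scale-free graphs: a
  hub's near-zero-lag relations with the synchronized cluster give it low
  PLI, and its leaves inherit its phase field.
* Euler–Maruyama at 1 ms is first-order; all reported patterns were
  checked against 5–10× finer steps.
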