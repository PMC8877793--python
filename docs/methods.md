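# Methods

## Model

`repsync` integrates two deterministic ODE systems.

**Classic repressilator** (`core_model.classic_rhs`): the standard
dimensionless three-gene repression cycle

    dm_i/dt = −m_i + α/(1 + p_{i−1}^n) + α_0
    dp_i/dt = −β (p_i − m_i)

with species index taken cyclically (the repressor of species 1 is
protein 3).

**Enzymatically coupled system** (`core_model.coupled_rhs`): three
repressilators built from independent species, degraded by one shared enzyme
pool with Michaelis–Menten kinetics:

    dm_{i,j}/dt = α_i/(1 + p_{i,j−1}^n) + α_{0,i} − k m_{i,j}/(K_m + Σ_{r,s} m_{r,s})
    dp_{i,j}/dt = β_i m_{i,j} − k p_{i,j}/(K_p + Σ_{r,s} p_{r,s})

The sums run over all nine mRNAs (resp. proteins); the shared denominator is
the only interaction between circuits. One maximum rate `k` serves both
channels (one enzyme pool degrades everything); enzymes are not modelled as
explicit species, only through this saturating rate law. Total degradation
flux is therefore bounded by `k` per channel regardless of load — the
saturation that produces the coupling.

## Parameters

All quantities are dimensionless (concentrations scaled as in the standard
repressilator non-dimensionalization; time in units of the mRNA lifetime of
the classic model).

| parameter | default | meaning |
|---|---|---|
| `n` | 2.4 | Hill cooperativity of repression |
| `α_0` | 0.1 | repressed-promoter (leak) transcription rate |
| `β` | 1.0 | protein/mRNA decay-rate ratio |
| `k` | 10.0 | maximum (saturated) degradation rate, both channels |
| `α_2` | 6.0 | central activation rate |
| `γ` | swept | activation-rate offset: `α = (α_2−γ, α_2, α_2+γ)` |
| `K_m`, `K_p` | swept | Michaelis constants of the two degradation channels |

γ must satisfy `0 ≤ γ < α_2` so the weakest circuit keeps a positive
activation rate. Small `K` means a strongly saturated enzyme pool, hence
strong indirect coupling; large `K` weakens the coupling but — because `k`
is held fixed — also weakens per-capita degradation, and beyond
`K_m = K_p ≈ 20–30` the system settles to a stable fixed point and no
periods are detectable at all. (The classic model is recovered only in the
joint limit `k = K_m = K_p → ∞`, which a test verifies at `10^4` on random
states.)

## Simulation

Initial conditions: all 18 concentrations i.i.d. uniform on [0, 1]
(`simulate.sample_initial_state`). Integration uses LSODA
(`scipy.integrate.odeint`) with `rtol = 1e-8`, `atol = 1e-10`, sampled every
`Δt = 0.05` on [0, 600]; the first `t_burn = 100` time units are discarded
before analysis so that measurements reflect the attractor. These choices
are the package's defaults, all overridable: the 500-unit analysis window
holds ≥13 cycles of the typical (period ≈ 37) oscillation and ≈8 of the
slowest period-doubled mode (≈ 64), and Δt is ≈ 0.1% of a period, far below
the one-lag quantization of the period estimate. Halving versus tightening
tolerances ten-fold moves detected periods by less than 1% (tested).

The right-hand sides are evaluated twice in the codebase: a plain-numpy
reference (`core_model`) defining the public contract, and numba kernels
(`_kernels`) used inside the integrator for speed; a test pins their
equality to 1e-13 on random states. Small negative concentrations produced
by adaptive stepping are clamped to zero inside the Hill terms and
saturation sums (`p^n` with non-integer `n` must not see negative values);
states are never modified, only the rate evaluation.

Reproducibility: a master seed and the grid/replicate indices derive
per-replicate seeds through `numpy.random.SeedSequence(master,
spawn_key=(cell, replicate))`, so sweep cells are independent, individually
reproducible, and identical regardless of evaluation order; fixed
(parameters, config, seed) replays are bit-identical.

## Period and synchronization measures

The normalized autocorrelation of a series of length N is computed after
mean removal, with the lag-k product sum truncated to the overlapping
samples (l = 0 … N−1−k) and normalized by the lag-0 term, so R(0) = 1
exactly. Truncation (rather than periodic wrap-around) avoids artifacts
from residual non-stationarity; its cost is a deterministic (1 − k/N)
shrinkage of R at large lags, which is why `max_lag` defaults to N/2 (at
least two cycles behind every reportable peak). The FFT implementation is
pinned to a direct O(N²) evaluation at 1e-10 by tests.

The period is τ = k̃·Δt where k̃ is the smallest lag with
R(k) > R(k−1), R(k) > R(k+1) and R(k) > 0.7 — strict comparisons, so
plateaus never qualify; the threshold is configurable. Periods are measured
on the first mRNA species (j = 1) of each repressilator. If no qualifying
lag exists the period is *undetected* — this happens both for damped
(non-oscillating) dynamics and for strongly modulated waveforms whose
autocorrelation peaks stay below threshold.

Synchronization: Δp = Σ_{i>j} (τ_i − τ_j)² over the three pairs;
permutation-invariant, non-negative, quadratic under rescaling, zero iff
all periods are equal. Because detected periods are integer multiples of
Δt, perfectly synchronized replicates give Δp = 0 exactly.

Diagnostics: `phase_lag` maximizes the normalized cross-correlation over
lags within half the dominant period; `power_spectrum` is the one-sided
periodogram with mean removal, with a helper extracting the top-q local
spectral maxima.

## Parameter sweep and aggregation

Each (γ, K_m = K_p) cell runs `n_reps` replicates from fresh uniform initial
conditions. Replicates with any undetected period are excluded from the
cell's mean Δp and counted in `frac_undetected` (default policy); an
alternative `penalize` policy assigns such replicates a worst-case
(max_lag·Δt)² per affected pair. Cells average Δp first, then take log10
for display, clamped below at `log_floor = −6` (log of the exactly-zero
Δp of synchronized cells); cells where *no* replicate defines Δp are NaN.

`find_gamma_transition` returns the midpoint of the adjacent γ pair with
the largest absolute jump in log10 mean Δp along one K column, skipping
NaN cells. `find_asynchronous_island` scans level sets of the log10 map
from high to low, takes 4-connected components not touching the grid
boundary, and accepts the largest component whose minimum exceeds the
maximum over its 8-connected surrounding ring by the required contrast
(default 1). `classify_coupling` labels a replicate fully/partially
coupled or uncoupled by counting period pairs within a relative tolerance
(default 2%, several lag-quantization steps at typical periods).

`single_network_failure_gamma` probes the mechanism of the sharp
transition — the weakest repressilator (α = α_2 − γ) losing the ability to
oscillate unassisted. Its default `shared_load` mode replicates that
circuit three-fold (all activation rates set to α_2 − γ in the coupled
system), preserving the total enzymatic load the circuit experiences inside
the full system; an `isolated` mode restricts the equations to one network
(saturation sums over its own three species only). The distinction matters:
an isolated network loads the enzymes three times less, so its per-capita
degradation `k/(K + Σ)` is far higher and oscillations die at much smaller
γ. The shared-load probe is the one that tracks the transition of the full
system (both are exercised in tests at K_m = K_p = 2).

## Observed map topology at the default settings

At K_m = K_p = 2 the γ scan shows the sharp regime change near γ ≈ 4
(acceptance script, `t1`), coinciding within ±0.2 with the shared-load
single-oscillator failure point; γ ≤ 1 rows of the reduced map lie below
the grid-median log10 mean Δp (tested). In the asynchronous region the
weakest oscillator runs a nearly doubled period while the other two stay
close — large Δp with all periods detected.

One caveat the acceptance artifacts make explicit: on the reduced grid
(K log-spaced over [0.3, 30], γ up to 4.5, 10 replicates), the
high-Δp region at γ ∈ [3.25, 4] extends down to the smallest Michaelis
constants probed (checked separately to K = 0.05), so it forms a band
touching the grid edge rather than a cluster whose entire surrounding ring
is ≥1 lower; `find_asynchronous_island` therefore reports no ring-bounded
island there and the acceptance script writes `t2: null`. Detection at the
edge of this region is marginal (first autocorrelation peaks near the 0.7
threshold), so the island's exact topology is sensitive to the measurement
window and threshold conventions documented above.

## What the simulations do and do not emulate

The generator produces deterministic ODE trajectories from random initial
conditions. It emulates resource-competition coupling among ideal
repression cycles; it does **not** include molecular (copy-number) noise,
explicit enzyme species or their depletion/renewal, transcription/
translation delays, dilution, cross-talk between species, or in-vitro
non-idealities such as enzyme aging. Passing tests therefore establish
properties of this mean-field model and its analysis pipeline, not
quantitative predictions for a wet-lab implementation.

## Problem sizes

Unit tests integrate 250–400 time units; the end-to-end checks use the full
default window (600) with 20 replicates per γ for the transition scan
(21 × 20 simulations) and 10 replicates per cell for the reduced map
(17 × 10 × 10 in the test suite's extended grid; 11 × 10 × 10 in the
acceptance script). Larger grids and the 100-replicate ensemble behind the
full heatmap are available through `repsync sweep` configuration.

## Known limitations

* Exactly three repressilators with three species each; the state layout is
  fixed (generalization is out of scope).
* K_m and K_p are tied in the default sweep (independent variation is
  available in the API but unmapped).
* The period estimate is quantized to the lag grid (one Δt) and undefined
  for constant series; the autocorrelation threshold rule cannot separate
  "no oscillation" from "oscillation with strongly modulated envelope".
* No bifurcation continuation: transition locations are grid-resolution
  limited (±half a grid step).
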