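# repsync

Simulation and analysis of **synchronization between repressilators that are
coupled only through competition for shared degradation enzymes**.

In molecular programming (e.g. PEN-DNA-toolbox reaction networks), several
copies of an oscillator can be built from chemically independent species that
are all degraded by the same enzyme pool. Even with no direct interaction,
the oscillators couple *indirectly*: every species loads the enzymes, so each
one's effective degradation rate depends on everyone else's concentration.
`repsync` maps when this resource competition synchronizes three
repressilators, when it fails to, and where the transitions lie — information
useful for designing molecular controllers that can be switched in and out of
synchrony by modulating enzymatic saturation.

## Model

A single repressilator (three species in a repression cycle) in dimensionless
form:

```
dm_i/dt = −m_i + α/(1 + p_{i−1}^n) + α_0
dp_i/dt = −β (p_i − m_i)
```

Three such circuits (index *i*), each built from its own species (index *j*),
sharing one pool of degradation enzymes with Michaelis–Menten kinetics:

```
dm_{i,j}/dt = α_i/(1 + p_{i,j−1}^n) + α_{0,i} − k·m_{i,j}/(K_m + Σ_{r,s} m_{r,s})
dp_{i,j}/dt = β_i·m_{i,j} − k·p_{i,j}/(K_p + Σ_{r,s} p_{r,s})
```

The saturating denominators sum over **all nine** mRNA (resp. protein)
species — that shared load is the only coupling. Reference parameters:
`n = 2.4`, `α_0 = 0.1`, `β = 1`, `k = 10`, and activation rates
`(α_2 − γ, α_2, α_2 + γ)` with `α_2 = 6`, so the offset γ controls how
dissimilar the three oscillators are. Initial concentrations are drawn
uniformly on [0, 1].

Each oscillator's period τ_i is the first strict local maximum of its
normalized autocorrelation exceeding 0.7, measured on the first mRNA species;
synchronization is summarized by

```
Δp = Σ_{i>j} (τ_i − τ_j)²
```

(Δp = 0 ⇔ all periods equal). Sweeping (K_m = K_p, γ) with replicate
averaging yields a log₁₀ mean Δp heatmap whose main features are a
synchronized band at small γ, an asynchronous region at intermediate
saturation where the weakest oscillator runs a period-doubled mode, and a
sharp transition near γ ≈ 4 where that oscillator can no longer sustain
oscillations on its own and becomes driven by the other two.

## Worked example

One simulation inside the asynchronous region (γ = 3.2, K_m = K_p = 2):

```
$ repsync simulate --gamma 3.2 --km 2.0 --kp 2.0 --seed 1 --out demo
repressilator 1: period=63.25
repressilator 2: period=37.25
repressilator 3: period=37.80
delta_p: 1324.0050000006022
```

The weakest oscillator (α₁ = 6 − 3.2 = 2.8) has locked onto a nearly doubled
period, so Δp is large — the circuits are not period-synchronized. Compare a
strongly coupled, nearly homogeneous setting (γ = 0.5, K_m = K_p = 1):

```
$ repsync simulate --gamma 0.5 --km 1.0 --kp 1.0 --seed 1 --out demo2
repressilator 1: period=37.45
repressilator 2: period=37.35
repressilator 3: period=37.35
delta_p: 0.020000000000009094
```

All three periods agree to within the sampling resolution (Δt = 0.05), i.e.
the enzyme competition has synchronized them. Each run also writes a tidy
trajectory CSV, a JSON sync report, and a manifest sufficient to re-run it
bit-identically. `repsync sweep` produces the (K_m = K_p, γ) heatmap
(`--quick` for a coarse smoke-test grid), `repsync analyze` re-runs the
period analysis on an existing trajectory CSV, and `repsync fixtures` writes
deterministic synthetic test signals.

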