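# hemoconn

Functional and effective connectivity of slow hemodynamic oscillations.

`hemoconn` is for researchers who record multi-channel hemoglobin signals
(fNIRS Δ[HbO₂]) over several cortical regions and want to quantify how
those regions interact in the physiological frequency intervals
I 0.6–2 Hz (cardiac), II 0.145–0.6 Hz (respiratory), III 0.052–0.145 Hz
(myogenic) and IV 0.021–0.052 Hz (neurogenic) — for example to compare a
patient group against controls across postural conditions.

Two estimators form the core:

* **Wavelet phase coherence (WPCO)** — undirected functional connectivity.
  With W₁(t,f), W₂(t,f) the Morlet wavelet coefficients of two channels and
  Δφ their phase difference,

      WPCO(f) = √(⟨cos Δφ⟩²_t + ⟨sin Δφ⟩²_t) ∈ [0, 1],

  averaged over cone-of-influence-free times, then over each band's
  frequencies, then over inter-region channel pairs (15 undirected region
  pairs for the 6-region montage).

* **Coupling strength (CS)** — directed effective connectivity.  Each pair
  of band-limited phases is modelled as coupled stochastic phase
  oscillators, φ̇ᵢ = Σ_k c_k⁽ⁱ⁾ Φ_k(φ₁, φ₂) + ζᵢ, with Fourier base
  functions Φ_k up to order K = 2, inferred by recursive dynamical Bayesian
  inference; CS(j→i) is the norm of the coefficients in oscillator i's
  equation that involve φⱼ (30 directed region pairs).

Both are tested for significance against 100 amplitude-adjusted Fourier
transform (AAFT) surrogates (mean + 2 SD criterion).  A statistics layer
adds mixed 2×2 ANOVA, one-way ANOVA, repeated-measures comparison, t-tests
on cognitive scores (MMSE/MoCA) and Pearson correlations.  Because studies
of this kind rarely deposit raw recordings, the package includes a
synthetic-cohort generator with known directed coupling, so the whole
pipeline is testable against ground truth.

## Worked example

Infer the directed coupling of a simulated oscillator pair in which the
0.16 Hz oscillator drives the 0.10 Hz oscillator with amplitude
0.3 rad/s (phase noise D = 0.05 rad²/s, 600 s):

```python
import hemoconn as hc

osc = [hc.OscillatorSpec(0.10, 0.05), hc.OscillatorSpec(0.16, 0.05)]
phi = hc.simulate_coupled_phases(osc, [hc.CouplingSpec(1, 0, 0.3)],
                                 duration=600, dt=0.01, seed=11)
phases = hc.decimate_phases(phi, 0.01, 2.0)
result = hc.PhaseCouplingModel(phases[0], phases[1], fs=2.0,
                               f_lo=0.052).fit()
print(result.summary())
```

```
Phase coupling model (dynamical Bayesian inference)
  basis order K = 2 (25 base functions per equation)
  windows: 1 x 600 s, fs = 2 Hz, converged = True
  natural frequencies: f1 = 0.1004 Hz, f2 = 0.1629 Hz
  coupling strength: CS(2→1) = 0.2928, CS(1→2) = 0.0729 rad/s
  noise matrix D = [[0.0967 0.002 ]
 [0.002  0.094 ]]
```

The natural frequencies are recovered to within 2%, the driving direction
is found near its true amplitude (0.29 vs 0.3 rad/s), the absent reverse
direction sits at its noise floor (0.07, non-significant against AAFT
surrogates), and the residual noise matrix matches the theoretical value
2D = 0.1.

The full study pipeline (simulate → artifact correction → WPCO → CS →
group statistics) runs from the shell:

```
hemoconn run-all --config demo --seed 1 --out demo_run
```

which writes recording CSVs, FC/EC edge lists (TSV), a statistics table
and a manifest with config, seeds and output hashes under `demo_run/`.
A YAML config replaces `demo` for real layouts; `hemoconn simulate`,
`preprocess`, `fc`, `ec` and `stats` run prefixes of the same pipeline.

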