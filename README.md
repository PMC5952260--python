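# t2ivim

Extended T2-IVIM modelling of multi-b / multi-TE diffusion-weighted MRI.

## The problem

The intravoxel incoherent motion (IVIM) model describes DWI signal decay in
perfused tissue as a bi-exponential,

```
S(b) = S0 [ f e^(−b D*) + (1 − f) e^(−b D) ]
```

with a flow-like pseudo-diffusion compartment (fraction `f`, coefficient
`D*`) and true tissue diffusion (`D`). Conventional fits absorb all echo-time
(TE) weighting into `S0`, implicitly assuming both compartments share one
transverse relaxation time. They do not: blood T2 exceeds tissue T2, so the
fast compartment is *under-attenuated* at the echo time actually used, and a
single-TE fit overestimates `f` — by an amount that grows with TE and differs
between scanners and protocols. That makes `f` hard to compare across sites,
which matters wherever it is used as a perfusion biomarker (liver imaging,
oncology trials).

The extended **T2-IVIM** model gives each compartment its own relaxation
time,

```
S(b, TE) = S0 [ f e^(−b D*) e^(−TE/T2p) + (1 − f) e^(−b D) e^(−TE/T2t) ]
```

so that fitting data acquired at several (b, TE) combinations yields a
TE-independent `f` together with direct estimates of the compartment T2s
(`T2p` pseudo-diffusion / blood, `T2t` tissue). The apparent fraction a
single-TE fit would report is the closed form

```
f_app(TE) = f e^(−TE/T2p) / [ f e^(−TE/T2p) + (1 − f) e^(−TE/T2t) ]
```

which equals `f` only at TE = 0 or when T2p = T2t.

## What the package provides

- `t2ivim.models` — the two signal equations and `apparent_fraction`.
- `t2ivim.acquisition` — b–TE scheme tables (CSV) and three named liver
  protocols: a 6 b-value × 5 TE exploratory grid (`protocol1`), a
  clinical-style 15-combination scheme (`protocol2`), and its time-reduced
  subset (`protocol2_minimal`).
- `t2ivim.fitting` — bounded trust-region least squares with segmented
  initialization (mono-exponential high-b fit for `D`, back-projection to
  b = 0 for `f`, multi-TE log-linear fit at b = 50 for the `T2t` seed),
  for ROI-mean series and voxel-wise parameter maps (NIfTI in/out).
- `t2ivim.phantom` — synthetic liver-like phantoms with vessel structures,
  Rician noise at configurable SNR, and ground-truth maps.
- `t2ivim.stats` — TE-dependence tables, percent overestimation of `f`,
  cohort summaries, and the repeated-measures coefficient of variation on
  log-transformed values.
- `t2ivim.cli` — `t2ivim fit | simulate | table1 | cov` subcommands with
  resolved-config persistence for reproducible runs.

## Worked example

```python
import numpy as np
import t2ivim as tv

truth = tv.T2IVIMParams(S0=100, f=0.18, D=1.07e-3, Dstar=0.15,
                        T2p=77.6, T2t=42.1)
series = tv.simulate_series(truth, tv.protocol2(), SNR=np.inf)

# conventional single-TE IVIM fit at the minimum TE (62 ms)
f_ivim = tv.fit_ivim(series.at_TE(62.0)).params.f
# extended fit using all (b, TE) data
fit = tv.fit_t2ivim(series)

print(f"IVIM f at TE=62:  {f_ivim:.4f}")
print(f"T2-IVIM f:        {fit.params.f:.4f}")
print(f"T2t: {fit.params.T2t:.1f} ms, T2p: {fit.params.T2p:.1f} ms")
print(f"predicted f_app:  "
      f"{tv.apparent_fraction(0.18, 77.6, 42.1, 62.0):.4f}")
```

prints

```
IVIM f at TE=62:  0.3010
T2-IVIM f:        0.1800
T2t: 42.1 ms, T2p: 77.6 ms
predicted f_app:  0.3010
```

The single-TE fit reports 0.301 — a 67% overestimate of the true fraction
0.18, exactly the closed-form `f_app` at 62 ms — while the extended model
recovers the generating parameters. On noisy data the same pipeline runs
voxel-wise (`tv.fit_voxelwise`) to produce `f`, `D`, `D*`, `T2p`, `T2t`,
`f·D*` and apparent-`f` maps.

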