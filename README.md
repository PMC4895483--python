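# nitrite-chemostat

A kinetic model of nitrite utilization by *Escherichia coli* growing
anaerobically in a flow chemostat, for systems biologists studying how the
cell keeps intracellular nitrite low across a wide range of external supply.

Nitrite is toxic, and *E. coli* runs two reduction routes with opposite
placement and regulation: the periplasmic, respiratory NrfA reductase
(active form NrfA₂B₂, dominant at low nitrite) and the cytoplasmic,
detoxifying NirB reductase (active form NirB₂D, dominant at high nitrite),
fed by the pentameric NirC transporter. The package models a chemostat
experiment in which the *added nitrite* s — the concentration the vessel
would reach without cells — is varied, and the steady-state chemostat
nitrite u\*(s) and intracellular nitrite w\*(s) are observed.

The model couples three generalized-Hill regulatory inputs

```
m_Nrf(u) = (1 + δ₁(u/K₁)^h₁)/(1 + (u/K₁)^h₁) · (1 + δ₂(u/K₂)^h₂)/(1 + (u/K₂)^h₂)
m_Nir(u) = (1 + δ₁(u/K₁)^h₁ + δ₂(u/K₂)^h₂)/(1 + (u/K₁)^h₁ + (u/K₂)^h₂)
U(s)     = (y₁ + δ·y₂ + ω₂y₃)/(1 + y₁ + y₂ + ω₁y₃),   yᵢ = (s/Kᵢ)^hᵢ
```

to an 18-variable disequilibrium mass-action system: chemostat flow,
enzyme–substrate binding written as k_dis(E·S/K_M − ES), catalysis,
complex assembly (NrfAB/NrfA₂B₂, NirB₂/NirB₂D, NirC₅), protein synthesis,
degradation and growth dilution, and membrane-potential-modulated
translocation of the Nrf subunits into the periplasm at rate
kt(s) = kt_cp·(1 + d_U·U(s)). The analysis instrument is the positive
stationary point of the system at each s, found by damped Newton iteration
with an analytic Jacobian (stiff-integration fallback) and tracked over an
s grid by continuation, with a flux decomposition into the periplasmic,
import, export and cytoplasmic rates. Named model variants reproduce the
comparison experiments (potential-free regulation, constitutive *nrf*
expression, tight-export transporter), and a calibration layer fits the
Hill inputs to expression data and free kinetic parameters to an
accumulation curve. See `docs/methods.md` for the full model description.

## Worked example

Fit the expression inputs to synthetic activity data, calibrate the shared
Nrf synthesis rate against an accumulation curve, and inspect steady states:

```python
import numpy as np
from nitrite_chemostat import default_params, NitriteChemostatModel
from nitrite_chemostat.synthetic import gen_expression_dataset, gen_accumulation_dataset

params = default_params()
expr = gen_expression_dataset(params.nrf_expr, params.nir_expr, seed=1)
acc = gen_accumulation_dataset(params, noise_sd=0.02, seed=2)

model = NitriteChemostatModel(accumulation=acc, expression=expr, params=params)
res = model.fit(free=("turnover.ks_nrf",), seed=0, n_restarts_expression=8)
print(res.summary())
for r in res.scan(np.array([0.5, 2.0, 5.0])).results:
    print(f"s={r.s_added:.1f} mM  u*={r.state.u:.4f} mM  w*={r.state.w*1e3:.2f} uM  "
          f"J_nrfA={r.fluxes.J_nrfA:.3f}  J_nirB={r.fluxes.J_nirB:.3f} mM/s")
```

prints (abridged)

```
nrf expression fit   SSR = 0.01965   restarts = 8
    delta_nrf_1                  1.99062
    ...
kinetic calibration   SSR = 0.0207 mM^2   restarts = 1
    turnover.ks_nrf              5.06786e-06
====================================================================
s=0.5 mM  u*=0.0026 mM  w*=0.00 uM  J_nrfA=0.274  J_nirB=0.000 mM/s
s=2.0 mM  u*=0.0243 mM  w*=0.01 uM  J_nrfA=1.087  J_nirB=0.000 mM/s
s=5.0 mM  u*=2.5344 mM  w*=8.31 uM  J_nrfA=0.011  J_nirB=1.346 mM/s
```

The three rows show the two-regime structure: at 0.5 mM added nitrite the
periplasmic NrfA route consumes essentially all supply and chemostat
nitrite stays micromolar; at 5 mM the NrfA route is shut down by *nrf*
repression and the collapsed membrane potential, the NirC/NirB
import-and-reduce route carries the flux, nitrite accumulates to ~2.5 mM
in the vessel, and intracellular nitrite is held at ~8 μM. The fitted
`ks_nrf` lands within ~13 % of the generating value despite the 2 % noise
on the accumulation curve.

A command line mirrors the library:

```
nitrite-chemostat scan --smin 0 --smax 7 --points 50 --out scan.csv
nitrite-chemostat variant --name no_potential --out variant.toml
nitrite-chemostat scan --params variant.toml --out variant_scan.csv
nitrite-chemostat report --out report/
```

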