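# Methods

## The model

`nitrite_chemostat` implements a kinetic model of nitrite utilization by
*Escherichia coli* growing anaerobically in a flow chemostat. The chemostat
supplies nitrite at a constant rate; at steady state the culture's specific
growth rate equals the dilution rate `kflow`. The independent variable of
every experiment is the *added nitrite* `s` — the concentration that would
establish in the vessel without cells (inflow `V_in = kflow·s`).

Eighteen state variables evolve under mass-action/Michaelis–Menten kinetics:
chemostat nitrite `u`, intracellular nitrite `w`, and sixteen protein
species covering the three subsystems of nitrite handling:

* **Periplasmic reduction.** NrfA and NrfB monomers are synthesized in the
  cytoplasm from the *nrf* operon, translocate across the inner membrane,
  and assemble in the periplasm (NrfA + NrfB ⇌ NrfAB, 2 NrfAB ⇌ NrfA₂B₂).
  The NrfA₂B₂ heterotetramer reduces chemostat nitrite directly.
* **Transport.** NirC monomers pentamerize (5 NirC ⇌ NirC₅, an explicit
  fifth-order reaction with effective dissociation constant
  `K_dis_C5 = (k_dis/k_form)^{1/4}`); the pentamer carries both import
  (`u` → `w`) and export (`w` → `u`).
* **Cytoplasmic reduction.** NirB dimerizes and binds NirD
  (2 NirB ⇌ NirB₂, NirB₂ + NirD ⇌ NirB₂D); the NirB₂D trimer reduces
  intracellular nitrite.

Catalytic steps use a *disequilibrium* Michaelis–Menten form: the
enzyme–substrate complex is a state variable, binding proceeds at net rate
`k_dis·(E·S/K_M − ES)` — here `K_M` is the ratio `k_dis/k_assoc` of the
binding step, not the classical `(k_dis+k_cat)/k_assoc` — and catalysis at
`k_cat·ES`. Every protein species decays at a first-order rate and all
intracellular species are diluted at `kflow` (growth-synchronized
dilution). Fluxes from within-cell processes enter the chemostat balance
scaled by the cell volume fraction `C`; translocation into the periplasm is
concentrated by the cell-to-periplasm volume ratio `delta_peripl`.

Three phenomenological generalized-Hill inputs close the model:

* `m_Nrf(u)` — *nrf* expression efficiency, a product of an activating and
  a repressing Hill factor (unimodal, peak below 1 mM);
* `m_Nir(u)` — *nir* expression efficiency, a two-term rational Hill form
  (monotone increasing, saturating in the millimolar range);
* `U(s)` — the *nominal membrane potential*, a bounded unimodal function
  of added nitrite standing in for the proton-motive force. It modulates
  the cytoplasm→periplasm translocation rate as
  `kt_cp(s) = kt_nrf_cp·(1 + d_U·U(s))`.

Known typographic inconsistencies in the source equations (duplicate
labels, a transposed species in the cytoplasmic-reduction block, a
monomer/complex mix-up in the pentamer reaction, and a degradation sign)
are resolved in the only way that preserves elementary-reaction symmetry
and mass conservation; the tests verify that the nitrite-weighted sum of
the right-hand side reduces exactly to inflow − outflow − catalysis −
dilution (a sympy cross-check repeats the reduction symbolically).

## Steady-state analysis

The unit of analysis is the positive stationary point at fixed `s`. The
solver runs a damped Newton iteration with the analytic 18×18 Jacobian and
an Armijo backtracking line search, falling back to a scaled Powell hybrid
solve and, if needed, stiff integration (LSODA with analytic Jacobian,
Radau as backup) to t = 10⁷ s followed by a Newton polish. Convergence
means max |du/dt| < 1e-10 mM/s on a nonnegative state; failures are
reported explicitly, never returned as partial answers. `scan` tracks the
solution along an increasing `s` grid by continuation. The default grid is
50 log-spaced points on [0.01, 7] mM plus s = 0: the range covers both
utilization regimes, and the upper end was chosen because the high-nitrite
regime is fully established well below it.

Flux decomposition reports, per cell volume: periplasmic reduction
`J_nrfA = k_cat_nrf·NrfA2B2u`, import `J_import = k_cat_nirC_in·NirC5u`,
export `J_export = k_cat_nirC_out·NirC5w`, cytoplasmic reduction
`J_nirB = k_cat_nirB·NirB2Dw`, their total, and the population-level
consumption `kflow·(s−u)/C` inferred from the chemostat balance.

## Parameters

Units are mM and seconds throughout. Fixed, literature-anchored values:

| parameter | value | meaning |
|---|---|---|
| `kflow` | ln 2 / 4200 s⁻¹ | dilution = growth rate at a 70-min cell cycle |
| `C` | 3·10⁻⁴ | cell volume fraction (admissible 10⁻⁴–2·10⁻³) |
| `delta_peripl` | 6 | cell/periplasm volume ratio (admissible 2.5–12.5, from a periplasm occupying 8–40 % of cell volume) |
| `K_M_nrf` | 0.03 mM | NrfA Michaelis constant (measured at −0.4 V) |
| `K_M_nirC_in`, `K_M_nirC_out` | 1 mM | NirC transport constants transferred from *S. typhimurium* |
| `kt_nrf_cp` | 0.01 s⁻¹ | baseline translocation rate |
| cytoplasmic `k_d` | ln 2 / 7200 s⁻¹ | 2-h mean half-life |
| periplasmic `k_d` | ln 2 / 72000 s⁻¹ | order-of-magnitude higher stability |

`ks_nir_C ≥ 5·ks_nir_B` is enforced (NirC translation outpaces NirB at
least five-fold); NrfA and NrfB share one synthesis constant (equimolar
translation).

The remaining values — turnover numbers, assembly constants, synthesis
rates, the Hill-input shapes and the potential coupling `d_U` — were
calibrated, as in the original study, against the steady-state behaviour
the data fix: chemostat nitrite `u*(s)` tracking the accumulation curve
(low and weakly increasing below ~1.25 mM, rising into the millimolar
range above ~3.5 mM), intracellular nitrite capped at 14 μM and sitting in
the 6–15 μM band for s ∈ [4, 7] mM, import locked to cytoplasmic reduction
at high s, and essentially zero baseline export. The calibrated set is
committed as `src/nitrite_chemostat/data/default_params.toml` and is the
single source of defaults.

Two structural points the calibration surfaced, documented here because
they shape what the model can and cannot learn from data:

* The sensitivity of the Nrf branch to translocation is approximately
  quadratic: monomers exchange rapidly between compartments relative to
  their decay, so the periplasmic monomer level scales with `kt_cp`, and
  dimer assembly scales with its square. This is what makes the
  potential-modulated translocation an effective regulator at low `s`.
* The intracellular nitrite level is a *free characteristic*: parameters
  that rescale `w*` (the export constant `K_M_nirC_out`, equivalently the
  `K_dis` of the export complex, together with the NirC pool size) can
  move it by an order of magnitude without measurably changing `u*(s)`.
  The calibration therefore pins `w*` only through the documented
  micromolar bounds, and the parameter-recovery tests use identifiable
  parameter sets (e.g. `ks_nrf`, `ks_nir_C`, `K_M_nirC_in`, which control
  the low-s branch, the high-s level and the high-s shape respectively);
  `K_M_nirB` is structurally unidentifiable from an accumulation curve.

## Model variants

* `no_potential` — `d_U = 0` with the compensatory constitutive
  translocation rate 0.055 s⁻¹ (5.5× baseline): isolates the genetic
  component of Nrf regulation. The difference between full-model and
  variant periplasmic rates is a bell-shaped curve on (0, 2] mM — the
  activity the membrane potential adds.
* `constitutive_nrf` — `m_Nrf ≡ 1`, `m_Nir ≡ 0`, `ks_nrf = 4.5·10⁻⁶ mM/s`
  and a re-shaped potential profile. The printed override list
  (K₁ = 0.11, h₁ = 2, δ₂ = 0.0375, K₂ = 0.6, h₂ = 8, ω₂ = 0.005,
  K₃ = 2.2, h₃ = 15) is applied to the potential profile feeding
  translocation — the only nitrite-dependent input left once expression is
  constitutive; this mapping is interpretive and is noted as such.
* `export` / `free_intracellular` — `K_M_nirC_out = 0.003 mM` (300× tighter)
  with `ks_nir_C = 1.1·10⁻⁴ mM/s`. The two names document two claims about
  one parameter set (the override lists coincide once one recognizes the
  export-binding `K_dis` as the export `K_M`): export rises to a large
  fraction of import, and `w*` shifts more than ten-fold, while `u*(s)`
  stays within a few percent of base.

## Calibration machinery

`fit_expression_params` fits each operon's Hill input by multi-start
(default 32) trust-region least squares on log-transformed parameters;
bounds are δ ∈ [10⁻³, 10³], K ∈ [10⁻³, 50] mM, h ∈ [0.3, 20]. The
objective is unweighted SSR on the natural scale — the simplest defensible
choice absent a stated error model. `calibrate_kinetics` minimizes
Σ(u*_model(sᵢ) − u*_data(sᵢ))² with a continuation scan inside the
objective; solver failures at trial points are penalized and logged, never
fatal. Both are deterministic given a seed.

## Synthetic data

The study's expression and chemostat measurements are not numerically
tabulated, so the pipeline runs on generated stand-ins: Hill-function
activities and scan-derived accumulation curves under multiplicative
lognormal noise (σ = 0.05 by default; positivity makes a log-scale error
model the natural choice). The committed default parameters are the
generating truth for the packaged fixtures, and `calibrate-defaults`
demonstrates that refitting the expression blocks to the noiseless
fixtures recovers them to tight tolerance; an archived noisy refit could
not be bit-identical to hand-committed values, so exact regeneration is
deliberately not claimed. What passing tests show is therefore internal
consistency — the machinery recovers known truth under the declared noise
model — not agreement with any particular laboratory dataset; real assay
data would add day effects, heteroscedasticity and calibration drift that
the generator does not emulate, and `C` is held constant (fixed-density
culture) throughout.

## Numerical choices and degenerate inputs

* Residual tolerance 1e-10 mM/s; integration tolerances rtol 1e-8,
  atol 1e-14; trajectories evaluated on the nonnegative part of the state
  so solver round-off cannot feed back through fractional-power terms.
* Hill terms are evaluated at max(u, 0) inside the solver so Newton trial
  steps crossing zero remain finite.
* `s = 0` yields the nitrite-free equilibrium (protein pools at
  synthesis/decay balance); `C = 0` decouples the chemostat
  (`u* = s` exactly); both are covered by closed-form tests.
* Solutions with components below −10⁻⁹ mM are rejected as unphysical;
  round-off negatives above that are clamped to zero.
* Uniqueness is probed, not assumed: `uniqueness_probe` solves from
  dispersed starts and reports disagreement instead of resolving it.

## Known limitations

* NarK/NarU transport and mechanistic NarL/NarP/NarQ/NarX signalling are
  out of scope; the Hill inputs absorb them phenomenologically.
* The nominal potential is a stand-in shape, not an electrophysiological
  model; only its qualitative features (zero at zero, maximum between 0.1
  and 1 mM added nitrite, bounded tail) are meaningful.
* In the transition window between the two utilization regimes
  (s ≈ 2.5–3.2 mM) the steady state is a steep function of s; comparisons
  between parameter sets there are grid-sensitive.
* The import/export activity ratio of NirC and the absolute intracellular
  nitrite level are free parameters of the model family; nothing in an
  accumulation curve constrains them.
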