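# Methods

This note records the physical model behind the synthetic fixtures, the
estimators used to analyse them, and the scaling choices made so the
test and acceptance suites run in minutes.

## Dumbbell model and constants

A dual-trap dumbbell is modelled as two optical traps of combined
stiffness `k_eff` (default 0.15 pN/nm) in series with extensible
double-stranded handles (contour 1120 nm, persistence length 40 nm,
stretch modulus 1200 pN) and the single-stranded RNA released by
unfolding (0.65 nm/nt contour, persistence length 1.0 nm, Marko–Siggia
interpolation).  Each closed stem subtracts a fixed 2.0 nm helix width
from the released contour.  At fixed trap separation `D`, the force of a
state with `n` unfolded nucleotides solves
`F = k_eff · (D − x_handles(F) − x_ss(F, n))`.
Thermal energy is `kT = 4.114 pN·nm` at 25 °C; 1 kcal/mol = 6.948 pN·nm.

The total energy of a state at fixed `D` is its zero-force folding free
energy plus the worm-like-chain stretch energies of ssRNA and handles
plus the trap energy `F²/2k_eff`.  Transition rates follow a Bell model
evaluated at the departing state's force, with the reverse rate set from
the energy gap, so the stationary distribution of every fixture is
exactly Boltzmann in these total energies (detailed balance is an
acceptance property).  Simulation is exact continuous-time Markov
(Gillespie) sampling, binned to the recorded sampling rate, with
white Gaussian force noise (default SD 0.35 pN) added after state
averaging within each stored sample.

## Fixtures

Presets live in `src/otrna/data/*.yaml`:

- `CDE_two_state` — a 15-nt two-state hairpin (ΔG₀ 4.10 kcal/mol).  Its
  contour-length gain, 15 · 0.65 − 2.0 = 7.75 nm, is recovered from
  force-jump pairs in stretch–relax cycles.
- `ADE_six_state` — a six-state network F, I1…I3, U plus an off-pathway
  misfold M reachable only from I1, with zero-force energies up to
  22.19 kcal/mol and forces spanning 10.2–13.0 pN at the default
  separation.
- `ADE_extROQ_binding` — the two-state element with a binding block:
  conformational hopping modulated by a protein that binds the folded
  state (conformational selection), with per-condition zero-force
  K_D values.

Binding conditions used in the K_D recovery experiments pair a true
K_D with kinetic parameters: association rate 1 × 10⁷ M⁻¹s⁻¹, a total
off rate split 40 % force-independent / 60 % force-dependent, and a
Bell length Δx_off of 1.0–2.0 nm depending on condition.  Off rates are
measured at three forces per condition (e.g. 5/7/9 pN) chosen during
estimator design so that the zero-force extrapolation window stays
within the calibrated range.

## Estimators

- **HMM assignment** — Gaussian-emission HMM (hmmlearn), sticky
  transition prior 0.99, minimum covariance (0.05 pN)², means
  initialised from quantiles or supplied force levels, states relabelled
  by descending force.  Model size is chosen by BIC over 2–8 states
  unless fixed.  Dwells shorter than `min_dwell_samples` (default 3)
  are merged into their neighbours (instrument dead time).
- **Dwell-time fits** — exponential rate by maximum likelihood with
  exact gamma confidence intervals; dead-time truncation by shifted
  MLE; multi-exponential detection by 2-component EM accepted at
  ΔBIC > 6.
- **Bound-phase segmentation** — qualifying runs of the bound state
  longer than `min_duration`, with gaps shorter than `merge_gap`
  bridged; apparent off rates are corrected for missed short events via
  `p_detect = exp(−min_duration · k_off)` and on rates for fractional
  occupancy of the binding-competent conformation.
- **Force-dependent off rates** — weighted least squares on log rates
  over a grid of (Δx, force-independent fraction) with a closed-form
  scale; weights `1/(1/n + σ_sys²)`, σ_sys = 0.10.  Confidence
  intervals come from a profile-likelihood cut calibrated by parametric
  bootstrap (400 replicates), and a bootstrap bias correction is applied
  to the zero-force intercept only — the fitted curve itself reproduces
  the data inside the measured window.  With three forces and three
  parameters the point estimate is interpolatory, so the calibrated
  interval, not the point value, carries the inference; K_D intervals
  are propagated by interval arithmetic against the pooled on rate.
- **Energetics** — population free energies from dwell-weighted
  occupancies; zero-force extrapolation subtracts ssRNA and handle
  stretch energies and the trap-energy difference.  ΔΔG of protein
  stabilisation compares folded/unfolded occupancy ratios between bound
  and unbound phases, with a seeded bootstrap CI over dwells.
- **Network** — transition graph from the dwell sequence; a state whose
  observed neighbours form a pendant attachment off the main
  folding axis is labelled off-pathway.  Observed contour-length gains
  are matched (tolerance 1.5 nm) against intermediates enumerated from
  a dot-bracket structure by closing helices outside-in.
- **Bulk** — Hill fits with multistart over K_D decades and bounds-
  clipped initial fractions; melting curves fit by a double Boltzmann
  initialised from Savitzky–Golay derivative extrema, falling back to a
  single transition when one midpoint is unsupported; HNN-COSY
  couplings from `|J| = atan(√|I_cross/I_diag|)/(2πΔ)`, capped at
  `1/(4Δ)` at saturation.

## Problem-size choices

To keep the full suite within a laptop-scale budget, the package's own
test and acceptance experiments reduce acquisition relative to the
instrument defaults (78.125 kHz acquisition, 3× downsampling): passive
traces are typically simulated at 6–30 kHz acquisition and 8–60 s
duration, K_D conditions use three forces with 40–80 events each, ΔΔG
experiments use single traces per condition, and bootstrap sizes are
400–1000.  These are deliberate scalings of the same generative model —
all tolerances were chosen against these sizes and verified across
multiple seeds before being frozen.  The melting acceptance tolerance
(0.5 °C) reflects the 1 °C grid and the noise level of the simulated
absorbance curves.

Known limitations: dwell statistics at sampling rates comparable to the
hopping rate are dead-time limited (the reported rates then
underestimate truth unless `dead_time` is supplied); zero-force off-rate
extrapolation amplifies in-window uncertainty exponentially in Δx; and
misfold classification needs the stored sampling to resolve the shortest
dwells, otherwise skip-level transitions are fabricated by
discretisation.
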