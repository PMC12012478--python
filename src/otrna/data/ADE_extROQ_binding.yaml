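# Low-force three-state network (most-folded observed state I1, apical
# stem-loop I3, unfolded U) with a protein-binding channel emulating the
# extended ROQ domain at 10 nM: binding exclusively from the folded
# stem-loop I3 (conformational selection), unfolding of I3 blocked and
# refolding I3->I1 slowed 8.99x (= exp(1.3 kcal/mol / kT)) while bound.
# Off-rate has force-independent and Bell contributions with
# k_off(0) = 0.0167 /s, matching K_D = 1.67 nM at k_on = 1e7 /M/s.
# Conformational energies are synthetic calibrations at 621 nm trap
# separation (I3 at ~7 pN).
name: ADE_extROQ_binding
detailed_balance: true
elastic:
  kT_pN_nm: 4.114
  trap_stiffness_pN_per_nm: 0.15
  handle_contour_nm: 600.0
  handle_persistence_nm: 40.0
  handle_stretch_modulus_pN: 1000.0
  ss_contour_per_nt_nm: 0.65
  ss_persistence_nm: 1.0
  folded_offset_nm: 2.0
states:
  - {name: I1, n_unfolded_nt: 0, dG0_kcal_per_mol: 0.0}
  - {name: I3, n_unfolded_nt: 13, dG0_kcal_per_mol: 2.675}
  - {name: U, n_unfolded_nt: 34, dG0_kcal_per_mol: 5.610}
transitions:
  - {source: I1, target: I3, k0_per_s: 0.35103, dx_nm: 1.5, sign: 1}
  - {source: I3, target: U, k0_per_s: 1.55811, dx_nm: 1.5, sign: 1}
binding:
  k_on_per_M_per_s: 1.0e7
  protein_conc_M: 1.0e-8
  k_off0_per_s: 0.01
  dx_off_nm: 1.5
  k_off_independent_per_s: 0.00668
  competent_state: I3
  blocked_while_bound:
    - [I3, U]
  slowed_while_bound:
    - {edge: [I3, I1], factor: 8.99}
defaults:
  trap_separation_nm: 621.17
  duration_s: 300.0
  noise_sd_pN: 0.35
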