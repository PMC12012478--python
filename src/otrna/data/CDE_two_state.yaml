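# Two-state 15-nt hairpin (triloop-type constitutive decay element).
# Synthetic calibration: equal total energies at 657.5 nm trap separation,
# putting the folded/unfolded exchange midpoint at ~11.5 pN with ~1000/s
# hopping. Values chosen for internal consistency, not measured.
name: CDE_two_state
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
  - {name: F, n_unfolded_nt: 0, dG0_kcal_per_mol: 0.0}
  - {name: U, n_unfolded_nt: 15, dG0_kcal_per_mol: 4.103}
transitions:
  - {source: F, target: U, k0_per_s: 0.01327, dx_nm: 4.0, sign: 1}
defaults:
  trap_separation_nm: 657.53
  duration_s: 10.0
  noise_sd_pN: 0.35
  velocity_nm_per_s: 100.0
  f_range_pN: [2.0, 18.0]
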