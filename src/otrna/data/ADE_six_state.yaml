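# Six-state folding network of a hexaloop-type alternative decay element:
# F (fully folded), on-pathway intermediates I1/I2/I3, misfold M reachable
# only from I2, and the unfolded state U. Effective trap stiffness 0.2
# pN/nm (two 0.4 pN/nm traps). State energies are calibrated so all six
# states exchange within ~1.2 kT at 648 nm trap separation; Bell
# transition-state distances of 2 nm give 10-50/s unfolding rates there.
# Synthetic fixture values, not measured.
name: ADE_six_state
detailed_balance: true
elastic:
  kT_pN_nm: 4.114
  trap_stiffness_pN_per_nm: 0.2
  handle_contour_nm: 600.0
  handle_persistence_nm: 40.0
  handle_stretch_modulus_pN: 1000.0
  ss_contour_per_nt_nm: 0.65
  ss_persistence_nm: 1.0
  folded_offset_nm: 2.0
states:
  - {name: F, n_unfolded_nt: 0, dG0_kcal_per_mol: 0.0}
  - {name: I1, n_unfolded_nt: 15, dG0_kcal_per_mol: 8.689}
  - {name: I2, n_unfolded_nt: 21, dG0_kcal_per_mol: 11.949}
  - {name: I3, n_unfolded_nt: 28, dG0_kcal_per_mol: 15.375}
  - {name: M, n_unfolded_nt: 35, dG0_kcal_per_mol: 19.148, n_closed_stems: 1}
  - {name: U, n_unfolded_nt: 49, dG0_kcal_per_mol: 22.190}
transitions:
  - {source: F, target: I1, k0_per_s: 0.02700, dx_nm: 2.0, sign: 1}
  - {source: I1, target: I2, k0_per_s: 0.11674, dx_nm: 2.0, sign: 1}
  - {source: I2, target: I3, k0_per_s: 0.14046, dx_nm: 2.0, sign: 1}
  - {source: I2, target: M, k0_per_s: 0.03511, dx_nm: 2.0, sign: 1}
  - {source: I3, target: U, k0_per_s: 0.21651, dx_nm: 2.0, sign: 1}
defaults:
  trap_separation_nm: 648.04
  duration_s: 200.0
  noise_sd_pN: 0.35
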