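"""Physical constants and unit conversions used throughout the package.

All mechanics are done in piconewtons and nanometers, so energies are
naturally in pN·nm.  Folding free energies are reported in kcal/mol; the
single conversion constant lives here so every module agrees.
"""

#: Thermal energy kT at 25 °C, in pN·nm.
KT_ROOM_PN_NM: float = 4.114

#: 1 kcal/mol expressed in pN·nm per molecule (4184 J/mol / N_A / 1e-21).
PN_NM_PER_KCAL_MOL: float = 6.948

#: kT at 25 °C in kcal/mol (= 4.114 / 6.948 ≈ 0.592).
KT_ROOM_KCAL_MOL: float = KT_ROOM_PN_NM / PN_NM_PER_KCAL_MOL

#: Raw acquisition rate of the instrument emulated by the generator, in Hz.
RAW_SAMPLING_HZ: float = 78125.0

#: Integer downsampling factor applied before analysis.
DOWNSAMPLE_FACTOR: int = 3


def kcal_to_pn_nm(energy_kcal_mol: float) -> float:
    return energy_kcal_mol * PN_NM_PER_KCAL_MOL


def pn_nm_to_kcal(energy_pn_nm: float) -> float:
    return energy_pn_nm / PN_NM_PER_KCAL_MOL
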