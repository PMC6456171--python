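"""Registry of the published epithelium parameter sets.

Eight monolayers with measured 547-Da PEG permeability and TER, their
junction-geometry measurements (cell-boundary length per area l_cb,
tricellular pore density rho_tTJ) and the fitted structural-dynamics
parameters (p_break, R_strand).  Values are stored in the customary
reporting units (nm/s, Ohm cm^2, um^-1, um^-2, um^-1 s^-1, GOhm um) and
converted to SI on load for traceability.

The MDCK C7 p_break was not fitted: its tricellular pores alone account
for the measured permeability, so the value was derived from observed
break densities and is shipped as a constant.
"""

from __future__ import annotations

from .permeability import EpitheliumParams

# name: (P_exp nm/s, TER Ohm cm^2, l_cb um^-1, rho_tTJ um^-2,
#        p_break um^-1 s^-1, R_strand GOhm um)
_TABLE: dict[str, tuple[float, float, float, float, float, float]] = {
    "Caco-2":              (10.0, 220, 0.525, 0.130, 0.047, 7.65),
    "MDCK C7":             (1.0,  460, 0.424, 0.078, 0.005, 10.62),
    "MDCK IIa":            (4.3,  28,  0.484, 0.106, 0.032, 0.46),
    "MDCK IIb":            (0.8,  54,  0.185, 0.014, 0.029, 0.32),
    "MDCK IIc":            (2.9,  41,  0.311, 0.035, 0.038, 0.45),
    "MDCK IId":            (2.3,  30,  0.179, 0.014, 0.044, 0.20),
    "MDCK IIb ZO-1 KD":    (3.1,  62,  0.189, 0.015, 0.047, 0.45),
    "MDCK IId ZO-1/2 dKD": (26.0, 26,  0.200, 0.019, 0.084, 0.34),
}

#: The four wild-type MDCK II measurements.
MDCK_II_NAMES = ("MDCK IIa", "MDCK IIb", "MDCK IIc", "MDCK IId")

#: Averaged MDCK cell-geometry used for strand-number sweeps and
#: sensitivity analyses (mean over the published MDCK measurements).
MEAN_L_CB_PER_UM = 0.282
MEAN_RHO_TTJ_PER_UM2 = 0.049

#: Mean fitted dynamics of the four MDCK II datasets.
MDCK_II_MEAN_P_BREAK = 0.036      # um^-1 s^-1
MDCK_II_MEAN_R_STRAND = 0.36      # GOhm um


def load_presets() -> dict[str, EpitheliumParams]:
    """All published epithelium presets, in SI units, keyed by name."""
    out = {}
    for name, (p, ter, lcb, rho, pb, rs) in _TABLE.items():
        out[name] = EpitheliumParams.from_paper_units(
            name, P_exp_nm_s=p, TER_ohm_cm2=ter, l_cb_per_um=lcb,
            rho_ttj_per_um2=rho, p_break_per_um_s=pb, R_strand_gohm_um=rs)
    return out


def get_preset(name: str) -> EpitheliumParams:
    presets = load_presets()
    if name not in presets:
        raise KeyError(f"unknown epithelium preset {name!r}; "
                       f"known: {sorted(presets)}")
    return presets[name]


def mdck_ii_average() -> EpitheliumParams:
    """Average MDCK II parameter set (mean dynamics, mean cell geometry)."""
    return EpitheliumParams.from_paper_units(
        "MDCK II average",
        l_cb_per_um=MEAN_L_CB_PER_UM, rho_ttj_per_um2=MEAN_RHO_TTJ_PER_UM2,
        p_break_per_um_s=MDCK_II_MEAN_P_BREAK,
        R_strand_gohm_um=MDCK_II_MEAN_R_STRAND)


def mdck_c7_average_geometry() -> EpitheliumParams:
    """MDCK C7 dynamics combined with the mean MDCK cell geometry."""
    c7 = get_preset("MDCK C7")
    return EpitheliumParams.from_paper_units(
        "MDCK C7 (mean geometry)",
        l_cb_per_um=MEAN_L_CB_PER_UM, rho_ttj_per_um2=MEAN_RHO_TTJ_PER_UM2,
        p_break_per_um_s=c7.p_break / 1e6,
        R_strand_gohm_um=c7.r_strand / 1e3)
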