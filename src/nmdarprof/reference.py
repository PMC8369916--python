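"""Published functional parameters for the GluN1-P532H GRIN1 variant.

The package's worked examples and end-to-end checks use the published
characterization of NMDA receptors carrying the GluN1-P532H missense variant
(coexpressed with GluN2A or GluN2B) as generating ground truth for the
synthetic-data module and as inputs to the closed-form composite
calculations.  Concentrations are in the units conventional for each assay
(EC50 in uM, zinc IC50 in nM); potentiation is the fold ratio
I_after / I_before.
"""

from __future__ import annotations

# Agonist potency (uM) and sample sizes, oocyte TEVC
GLU_EC50_UM = {
    "GluN2A": {"WT": 6.4, "P532H": 105.0, "n_wt": 27, "n_mut": 26},
    "GluN2B": {"WT": 1.9, "P532H": 82.0, "n_wt": 12, "n_mut": 20},
}
GLY_EC50_UM = {
    "GluN2A": {"WT": 1.8, "P532H": 2.0, "n_wt": 11, "n_mut": 12},
    "GluN2B": {"WT": 0.45, "P532H": 0.34, "n_wt": 19, "n_mut": 16},
}

# Negative modulators
MG_IC50_UM = {  # at -60 mV
    "GluN2A": {"WT": 19.0, "P532H": 22.0, "n_wt": 16, "n_mut": 14},
    "GluN2B": {"WT": 38.0, "P532H": 35.0, "n_wt": 7, "n_mut": 7},
}
ZN_IC50_NM = {  # tricine-buffered, -20 mV; residual plateau ~37%
    "GluN2A": {"WT": 8.5, "P532H": 4.1, "n_wt": 12, "n_mut": 12},
}
ZN_RESIDUAL_MIN_PCT = 37.0

# MTSEA open-probability assay (GluN2A-A650C background), fold potentiation
MTSEA_POTENTIATION = {"WT": 3.26, "P532H": 8.04, "n_wt": 41, "n_mut": 34}
P_OPEN = {"WT": 0.26, "P532H": 0.11}

# Deactivation kinetics, 1 mM glutamate (ms / percent), GluN2A
DEACTIVATION_GLUN2A = {
    "WT": {"tau_fast": 48.0, "tau_slow": 268.0, "pct_fast": 64.0, "tau_w": 66.0},
    "P532H": {"tau_fast": 21.0, "tau_slow": 189.0, "pct_fast": 91.0, "tau_w": 26.0},
}
ISS_OVER_IPEAK_GLUN2A = {"WT": 0.77, "P532H": 0.88}
RISE_10_90_MS_GLUN2A = {"WT": 6.0, "P532H": 14.0}
PEAK_DENSITY_GLUN2A = {"WT": 144.0, "P532H": 47.0}  # pA/pF

# Surface expression (reporter assay), fraction of the paired WT ratio
SURFACE_OF_WT = {"GluN2A": 0.64, "GluN2B": 0.67, "n_experiments": 5}
TOTAL_OF_WT = {"GluN2A": 1.10, "GluN2B": 1.93}

# Composite charge-transfer indices as published (GluN2A)
CHARGE_TRANSFER_GLUN2A = {"synaptic": 0.22, "nonsynaptic": 0.004}
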