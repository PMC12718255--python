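"""Physical constants and assay-wide defaults.

All defaults describe the reference assay conditions: a *Gaussia*
luciferase (GLuc) reporter encapsulated in PMOXA-PDMS-PMOXA polymersomes,
read out on a plate reader at 2 s cadence, with a free-enzyme calibration
series of coelenterazine (CLZ) concentrations.
"""

AVOGADRO = 6.02214076e23
"""Avogadro constant, mol^-1 (exact, SI 2019)."""

K_CAT_GLUC = 17.0
"""GLuc turnover number for coelenterazine, s^-1."""

MW_GLUC = 19_900.0
"""GLuc molecular mass, Da."""

C_GLUC_REHYDRATION = 5.26e-6
"""Enzyme concentration applied during film rehydration, mol/L.

Consistent with 0.1 mg/mL at ~19 kDa; this is the lumen concentration
under statistical encapsulation.
"""

C_GLUC_CALIBRATION = 0.05e-6
"""Free-enzyme concentration of the calibration series, mol/L."""

CALIBRATION_VOLUME_ML = 0.05
"""Enzyme aliquot volume of a calibration well, mL (50 uL)."""

MEMBRANE_THICKNESS_NM = 14.0
"""Polymersome membrane thickness, nm."""

WELL_VOLUME_UL = 100.0
"""Total well volume after substrate injection, uL (50 + 50)."""

ALIQUOT_VOLUME_UL = 50.0
"""Vesicle (or free enzyme) aliquot volume per well, uL."""

CALIBRATION_CONCENTRATIONS_UM = (
    0.1, 0.5, 1.0, 2.0, 3.0, 5.0, 7.0, 10.0, 15.0, 20.0, 25.0, 30.0,
)
"""In-well substrate concentrations of the calibration series, uM."""

HILL_VMAX_AU = 1.14e8
"""Reference calibration: maximal 1 s peak intensity, a.u."""

HILL_K_HALF_UM = 9.8
"""Reference calibration: half-saturation substrate concentration, uM."""

HILL_COEF = 1.44
"""Reference calibration: Hill coefficient (positive cooperativity)."""

BASELINE_AU = 110.0
"""Instrument/background luminescence level, a.u. (buffer-only wells read < 114)."""

C_OUT_UM = 80.0
"""External (in-well) substrate concentration of the transport assay, uM."""

QUANTUM_YIELD_FACTORS = {"CLZ": 1.0, "CLZ-n": 13.9, "CLZ-I": 11.7}
"""Multiplicative intensity correction per substrate, mapping each
derivative into the native-CLZ calibration gauge (1 / relative quantum
yield: 7.2% for CLZ-n, 8.5% for CLZ-I)."""

MEASUREMENT_CADENCE_S = 2.0
"""Plate reader sampling interval, s; first sample at t = 2 s post injection."""

ASSAY_DURATION_S = 600.0
"""Transport-assay measurement window, s (10 min)."""

CALIBRATION_DURATION_S = 10.0
"""Free-enzyme flash measurement window, s."""

PEAK_TIME_S = 1.0
"""Time of the free-enzyme luminescence peak after injection, s; flash
traces are extrapolated back to this point."""
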