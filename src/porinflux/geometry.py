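"""Vesicle geometry and encapsulation arithmetic.

Deterministic bookkeeping from batch metadata (z-average diameter,
membrane thickness, vesicle concentration) to the quantities the
transport inference needs: lumen volume, expected enzymes per vesicle,
total encapsulated enzyme amount, the calibration correlation factor
F_C, the per-lumen porin concentration, and the assay-sensitivity bound.

Enzyme counts are statistical means of a Poisson-like loading process
and are kept as real numbers, never rounded to integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import (
    ALIQUOT_VOLUME_UL,
    AVOGADRO,
    C_GLUC_REHYDRATION,
    K_CAT_GLUC,
    MEMBRANE_THICKNESS_NM,
    MW_GLUC,
    WELL_VOLUME_UL,
)

__all__ = [
    "VesiclePrep",
    "EnzymeSpec",
    "PorinLoad",
    "EncapsulationSummary",
    "lumen_volume",
    "enzymes_per_vesicle",
    "enzymes_per_vesicle_from_mass",
    "encapsulated_amount",
    "correlation_factor",
    "porin_concentration",
    "assay_sensitivity",
    "summarize_encapsulation",
]

_NM3_TO_L = 1e-24


@dataclass
class VesiclePrep:
    """Geometry and concentration of one polymersome batch.

    Parameters
    ----------
    name : str
        Batch label (e.g. ``"PolGLOmpF"``).
    diameter : float
        z-average hydrodynamic diameter d_P, nm.
    membrane_thickness : float
        Membrane thickness r_M, nm.
    vesicle_concentration : float
        Polymersomes per mL applied to the well, N_P.
    pdi : float
        Polydispersity index (metadata only; the size distribution is
        not modelled).
    well_volume : float
        Total in-well volume after injection, uL.
    vesicle_aliquot_volume : float
        Vesicle aliquot added per well, uL.
    """

    name: str = ""
    diameter: float = 0.0
    membrane_thickness: float = MEMBRANE_THICKNESS_NM
    vesicle_concentration: float = 0.0
    pdi: float = 0.0
    well_volume: float = WELL_VOLUME_UL
    vesicle_aliquot_volume: float = ALIQUOT_VOLUME_UL

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"diameter must be > 0, got {self.diameter}")
        if self.membrane_thickness < 0:
            raise ValueError("membrane_thickness must be >= 0")
        if self.vesicle_concentration < 0:
            raise ValueError("vesicle_concentration must be >= 0")
        if self.pdi < 0:
            raise ValueError("pdi must be >= 0")

    @property
    def lumen_volume_l(self) -> float:
        """Inner (lumen) volume of one vesicle, L."""
        return lumen_volume(self.diameter, self.membrane_thickness)


@dataclass
class EnzymeSpec:
    """Reporter enzyme constants.

    ``applied_concentration`` is the concentration during film
    rehydration (and hence the lumen concentration under statistical
    encapsulation); ``calibration_concentration`` is the free-enzyme
    concentration of the calibration series. Both in mol/L.
    """

    molecular_mass: float = MW_GLUC
    k_cat: float = K_CAT_GLUC
    applied_concentration: float = C_GLUC_REHYDRATION
    calibration_concentration: float = 0.05e-6

    def __post_init__(self) -> None:
        for f in ("molecular_mass", "k_cat", "applied_concentration",
                  "calibration_concentration"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")


@dataclass
class PorinLoad:
    """Mean porin-trimer occupancy of a batch, from gel densitometry."""

    porin_name: str = ""
    trimers_per_vesicle: float = 0.0
    sem: float = 0.0

    def __post_init__(self) -> None:
        if self.trimers_per_vesicle < 0:
            raise ValueError("trimers_per_vesicle must be >= 0")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")


@dataclass
class EncapsulationSummary:
    """Derived encapsulation quantities for one batch (all SI: L, mol, mol/L)."""

    lumen_volume: float
    enzymes_per_vesicle: float
    total_inner_volume: float
    encapsulated_amount: float
    lumen_concentration: float
    porin_concentration: float = 0.0
    prep: VesiclePrep | None = field(default=None, repr=False)


def lumen_volume(diameter: float, membrane_thickness: float = MEMBRANE_THICKNESS_NM) -> float:
    """Inner volume of a vesicle with outer diameter ``diameter`` (nm), in L.

    V = (4/3) * pi * (d/2 - r_M)^3, zero when the membrane fills the
    whole sphere (d/2 <= r_M, e.g. micelles).
    """
    if diameter < 0:
        raise ValueError("diameter must be >= 0")
    if membrane_thickness < 0:
        raise ValueError("membrane_thickness must be >= 0")
    inner_radius = diameter / 2.0 - membrane_thickness
    if inner_radius <= 0:
        return 0.0
    return (4.0 / 3.0) * math.pi * inner_radius**3 * _NM3_TO_L


def enzymes_per_vesicle(lumen_volume_l: float, concentration: float = C_GLUC_REHYDRATION) -> float:
    """Expected enzymes per vesicle under statistical encapsulation.

    N = V * c * N_A with V in L and c in mol/L. This is a mean occupancy
    and may be fractional.
    """
    if lumen_volume_l < 0 or concentration < 0:
        raise ValueError("inputs must be >= 0")
    return lumen_volume_l * concentration * AVOGADRO


def enzymes_per_vesicle_from_mass(
    lumen_volume_l: float, mass_concentration_mg_ml: float, molecular_mass: float = MW_GLUC
) -> float:
    """As :func:`enzymes_per_vesicle` but from a mass concentration (mg/mL).

    Divides by the molecular mass first: c = (mg/mL) / MW in mol/L.
    0.1 mg/mL at ~19 kDa gives 5.26 uM, the reference lumen concentration.
    """
    if mass_concentration_mg_ml < 0:
        raise ValueError("mass concentration must be >= 0")
    molar = mass_concentration_mg_ml / molecular_mass  # (g/L) / (g/mol) = mol/L
    return enzymes_per_vesicle(lumen_volume_l, molar)


def encapsulated_amount(
    lumen_concentration: float,
    lumen_volume_l: float,
    vesicle_concentration: float,
    aliquot_volume_ml: float,
) -> float:
    """Total encapsulated enzyme amount in a well, mol.

    n = c_lumen * V_lumen * N_P * V_aliquot; linear in every argument.
    ``vesicle_concentration`` in vesicles/mL, ``aliquot_volume_ml`` in mL.
    """
    for name, v in (
        ("lumen_concentration", lumen_concentration),
        ("lumen_volume_l", lumen_volume_l),
        ("vesicle_concentration", vesicle_concentration),
        ("aliquot_volume_ml", aliquot_volume_ml),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    return lumen_concentration * lumen_volume_l * vesicle_concentration * aliquot_volume_ml


def correlation_factor(n_calibration: float, n_polymersome: float) -> float:
    """Correlation factor F_C = n_cal / n_encapsulated.

    Maps intensities measured on the (dilute) encapsulated enzyme pool
    onto the gauge of the free-enzyme calibration, exploiting the linear
    intensity response of the luciferase in enzyme amount.
    """
    if n_polymersome <= 0:
        raise ValueError("encapsulated amount must be > 0")
    return n_calibration / n_polymersome


def porin_concentration(trimers_per_vesicle: float, lumen_volume_l: float) -> float:
    """Porin-trimer concentration relative to the lumen volume, mol/L.

    c_Omp = (n_tri / N_A) / V_lumen per vesicle; independent of vesicle
    count since numerator and denominator both scale with it.
    """
    if trimers_per_vesicle < 0:
        raise ValueError("trimers_per_vesicle must be >= 0")
    if lumen_volume_l <= 0:
        raise ValueError("lumen_volume must be > 0")
    return trimers_per_vesicle / (AVOGADRO * lumen_volume_l)


def assay_sensitivity(mean_enzymes_per_vesicle: float, k_cat: float = K_CAT_GLUC) -> float:
    """Maximal per-trimer transport rate the assay can resolve, s^-1.

    The enzymatic capacity of a vesicle, N_GLuc * k_cat, bounds the influx
    it can report; valid under the <= 1 trimer per vesicle design.
    """
    if mean_enzymes_per_vesicle < 0 or k_cat < 0:
        raise ValueError("inputs must be >= 0")
    return mean_enzymes_per_vesicle * k_cat


def summarize_encapsulation(
    prep: VesiclePrep,
    enzyme: EnzymeSpec | None = None,
    porins: PorinLoad | None = None,
) -> EncapsulationSummary:
    """Full encapsulation summary for one batch."""
    enzyme = enzyme or EnzymeSpec()
    v_lumen = prep.lumen_volume_l
    aliquot_ml = prep.vesicle_aliquot_volume * 1e-3
    n_enc = encapsulated_amount(
        enzyme.applied_concentration, v_lumen, prep.vesicle_concentration, aliquot_ml
    )
    total_inner = v_lumen * prep.vesicle_concentration * aliquot_ml
    c_omp = 0.0
    if porins is not None and porins.trimers_per_vesicle > 0 and v_lumen > 0:
        c_omp = porin_concentration(porins.trimers_per_vesicle, v_lumen)
    return EncapsulationSummary(
        lumen_volume=v_lumen,
        enzymes_per_vesicle=enzymes_per_vesicle(v_lumen, enzyme.applied_concentration),
        total_inner_volume=total_inner,
        encapsulated_amount=n_enc,
        lumen_concentration=enzyme.applied_concentration,
        porin_concentration=c_omp,
        prep=prep,
    )
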