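"""Seeded generators of calibration series and assay trace bundles.

These emulate the statistical structure of the plate-reader data the
analysis assumes: flash-type free-enzyme calibration traces at the
twelve standard substrate concentrations, and glow-type vesicle traces
(porin batches plus porin-free control) at 2 s cadence over 10 min.

Noise model: one multiplicative log-normal factor per replicate trace
of the requested CV (replicate scatter in plate luminescence is
dominated by pipetting/well effects and scales with the signal), plus
additive per-point baseline jitter of sd 5 a.u. With ``noise_cv = 0``
the output is exactly noiseless, so the generated data satisfy the
calibration and flux-balance identities to machine precision.

The flash amplitudes of the calibration generator are anchored per
concentration so that the extrapolated 1 s peak (above baseline) equals
the Hill truth exactly, keeping the generator and the calibration model
in one intensity gauge; the assay simulator shares that gauge through
its default photon scale.

Each global seed expands deterministically into independent per-trace
substreams keyed by condition name and replicate, so adding a scenario
never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .constants import (
    CALIBRATION_CONCENTRATIONS_UM,
    CALIBRATION_DURATION_S,
    CALIBRATION_VOLUME_ML,
    C_GLUC_CALIBRATION,
    HILL_COEF,
    HILL_K_HALF_UM,
    HILL_VMAX_AU,
    PEAK_TIME_S,
    QUANTUM_YIELD_FACTORS,
)
from .geometry import VesiclePrep, enzymes_per_vesicle
from .simulate import (
    KineticParams,
    SubstrateSpec,
    VesicleSystem,
    default_grid,
    hill_fraction,
    simulate_vesicle_trace,
)

__all__ = [
    "ScenarioSpec",
    "GENERATOR_VERSION",
    "REFERENCE_BATCHES",
    "default_scenarios",
    "make_calibration_dataset",
    "make_assay_dataset",
]

GENERATOR_VERSION = "1.0"

BASELINE_JITTER_SD = 5.0  # a.u., per point, active only when noise_cv > 0

DEFAULT_BACKGROUND_RATE = 2e-4  # s^-1, slow permeation of the bare polymer membrane
DEFAULT_DEFECT_BURST_UM = 0.2  # uM, packing-defect burst at injection

REFERENCE_BATCHES: dict[str, dict] = {
    "control": dict(diameter=201.7, vesicle_concentration=3.5e12,
                    vesicle_concentration_sem=4.6e11, pdi=0.16,
                    trimers_per_vesicle=0.0, trimers_sem=0.0, k_transport=0.0),
    "OmpF": dict(diameter=146.7, vesicle_concentration=2.4e12,
                 vesicle_concentration_sem=2.4e11, pdi=0.10,
                 trimers_per_vesicle=0.20, trimers_sem=0.021, k_transport=10.8),
    "OmpFdelta": dict(diameter=175.1, vesicle_concentration=1.7e12,
                      vesicle_concentration_sem=2.04e11, pdi=0.18,
                      trimers_per_vesicle=0.030, trimers_sem=0.004, k_transport=78.0),
    "PhoE": dict(diameter=161.0, vesicle_concentration=4.1e11,
                 vesicle_concentration_sem=4.92e10, pdi=0.15,
                 trimers_per_vesicle=0.68, trimers_sem=0.082, k_transport=2.8),
}
"""Reference polymersome batches: DLS/NTA geometry, densitometric trimer
loads and the per-trimer transport rates used as ground truth."""


@dataclass
class ScenarioSpec:
    """One simulated assay condition with its full ground truth."""

    name: str
    prep: VesiclePrep
    trimers_per_vesicle: float = 0.0
    k_transport_truth: float = 0.0  # molecules/s per trimer
    substrate: SubstrateSpec = field(default_factory=SubstrateSpec)
    kinetics: KineticParams = field(default_factory=KineticParams)
    background_rate: float = DEFAULT_BACKGROUND_RATE
    defect_burst: float = DEFAULT_DEFECT_BURST_UM
    noise_cv: float = 0.05
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def system(self) -> VesicleSystem:
        return VesicleSystem(
            prep=self.prep,
            enzymes_per_vesicle=enzymes_per_vesicle(self.prep.lumen_volume_l),
            trimers_per_vesicle=self.trimers_per_vesicle,
            k_transport=self.k_transport_truth,
            background_rate=self.background_rate,
            defect_burst=self.defect_burst,
            substrate=self.substrate,
            kinetics=self.kinetics,
        )


def _substream(seed: int, label: str, replicate: int) -> np.random.Generator:
    """Per-trace RNG derived from the global seed and a stable label hash."""
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence((int(seed), key, int(replicate))))


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative factor with mean 1 and the requested CV."""
    sigma = np.sqrt(np.log1p(cv**2))
    return float(rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma))


def substrate_for(name: str) -> SubstrateSpec:
    specs = {
        "CLZ": SubstrateSpec("CLZ", 423.5, 3.9, 1.0),
        "CLZ-n": SubstrateSpec("CLZ-n", 457.5, 5.07, 0.072),
        "CLZ-I": SubstrateSpec("CLZ-I", 533.3, 4.8, 0.085),
    }
    try:
        return specs[name]
    except KeyError:
        raise KeyError(f"unknown substrate {name!r}; known: {sorted(specs)}") from None


def default_scenarios(
    names=("control", "OmpF", "OmpFdelta", "PhoE"),
    substrate: str = "CLZ",
    noise_cv: float = 0.05,
    n_replicates: int = 3,
) -> list[ScenarioSpec]:
    """Scenario list from the reference batches (control included)."""
    out = []
    for name in names:
        b = REFERENCE_BATCHES[name]
        prep = VesiclePrep(name=name, diameter=b["diameter"],
                           vesicle_concentration=b["vesicle_concentration"],
                           pdi=b["pdi"])
        out.append(ScenarioSpec(
            name=name, prep=prep,
            trimers_per_vesicle=b["trimers_per_vesicle"],
            k_transport_truth=b["k_transport"],
            substrate=substrate_for(substrate),
            noise_cv=noise_cv, n_replicates=n_replicates,
        ))
    return out


def make_calibration_dataset(
    hill_truth: tuple[float, float, float] = (HILL_VMAX_AU, HILL_K_HALF_UM, HILL_COEF),
    kinetics: KineticParams | None = None,
    noise_cv: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
    concentrations=CALIBRATION_CONCENTRATIONS_UM,
) -> tuple[pd.DataFrame, dict]:
    """Synthetic free-enzyme calibration traces at the standard series.

    Flash traces sampled every 2 s over 10 s per concentration and
    replicate; the decay rate follows the turnover-inactivation
    mechanism (k1 = p_inact k_cat H(c)) and the amplitude is anchored so
    the extrapolated 1 s peak above baseline equals the Hill truth.

    Returns a long-format frame with columns ``concentration_uM,
    replicate, time_s, intensity_au`` and a truth manifest.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    kin = kinetics or KineticParams()
    v_max, k_half, h = hill_truth
    grid = np.arange(2.0, CALIBRATION_DURATION_S + 1.0, 2.0)
    rows = []
    for c in concentrations:
        H = hill_fraction(c, k_half, h)
        v_true = v_max * H
        k1 = kin.p_inact * kin.k_cat * H
        amplitude = v_true * np.exp(k1 * PEAK_TIME_S)
        clean = kin.baseline + amplitude * np.exp(-k1 * grid)
        for rep in range(1, n_replicates + 1):
            rng = _substream(seed, f"cal:{c:g}", rep)
            if noise_cv > 0:
                trace = clean * _lognormal_factor(rng, noise_cv)
                trace = trace + rng.normal(0.0, BASELINE_JITTER_SD, size=grid.size)
            else:
                trace = clean
            for t, y in zip(grid, trace):
                rows.append((float(c), rep, float(t), float(y)))
    df = pd.DataFrame(rows, columns=["concentration_uM", "replicate", "time_s", "intensity_au"])
    manifest = {
        "generator_version": GENERATOR_VERSION,
        "kind": "calibration",
        "seed": int(seed),
        "noise_cv": float(noise_cv),
        "n_replicates": int(n_replicates),
        "baseline_jitter_sd": float(BASELINE_JITTER_SD if noise_cv > 0 else 0.0),
        "hill_truth": {"v_max": float(v_max), "k_half": float(k_half), "h": float(h)},
        "kinetics": {"k_cat": kin.k_cat, "p_inact": kin.p_inact, "baseline": kin.baseline},
        "concentrations_uM": [float(c) for c in concentrations],
        "times_s": [float(t) for t in grid],
    }
    return df, manifest


def make_assay_dataset(
    scenarios: list[ScenarioSpec],
    seed: int = 0,
    grid=None,
) -> tuple[pd.DataFrame, dict]:
    """Synthetic glow-trace bundle for a list of scenarios.

    One noiseless mean-field simulation per scenario; replicate noise on
    top. Include a zero-trimer control scenario (sharing ``k_bg`` and
    ``defect_burst`` with the porin scenarios) whenever inference on the
    bundle is intended. Returns a long-format frame with columns
    ``condition, replicate, time_s, intensity_au`` plus a truth manifest.
    """
    names = [s.name for s in scenarios]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate scenario names in {names}")
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)

    rows = []
    manifest_scen = {}
    for scen in scenarios:
        clean = simulate_vesicle_trace(scen.system(), grid).intensities
        for rep in range(1, scen.n_replicates + 1):
            rng = _substream(seed, f"assay:{scen.name}", rep)
            if scen.noise_cv > 0:
                trace = clean * _lognormal_factor(rng, scen.noise_cv)
                trace = trace + rng.normal(0.0, BASELINE_JITTER_SD, size=grid.size)
            else:
                trace = clean
            for t, y in zip(grid, trace):
                rows.append((scen.name, rep, float(t), float(y)))
        manifest_scen[scen.name] = {
            "prep": {k: float(v) if isinstance(v, (int, float)) else v
                     for k, v in asdict(scen.prep).items()},
            "trimers_per_vesicle": float(scen.trimers_per_vesicle),
            "k_transport_truth": float(scen.k_transport_truth),
            "substrate": scen.substrate.name,
            "relative_quantum_yield": float(scen.substrate.relative_quantum_yield),
            "yield_factor": float(QUANTUM_YIELD_FACTORS.get(scen.substrate.name,
                                  1.0 / scen.substrate.relative_quantum_yield)),
            "background_rate": float(scen.background_rate),
            "defect_burst_uM": float(scen.defect_burst),
            "noise_cv": float(scen.noise_cv),
            "n_replicates": int(scen.n_replicates),
            "enzymes_per_vesicle": float(enzymes_per_vesicle(scen.prep.lumen_volume_l)),
        }
    df = pd.DataFrame(rows, columns=["condition", "replicate", "time_s", "intensity_au"])
    manifest = {
        "generator_version": GENERATOR_VERSION,
        "kind": "assay",
        "seed": int(seed),
        "calibration_enzyme_amount_mol": float(C_GLUC_CALIBRATION * CALIBRATION_VOLUME_ML * 1e-3),
        "times_s": [float(grid[0]), float(grid[-1]), float(grid[1] - grid[0])],
        "scenarios": manifest_scen,
    }
    return df, manifest
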