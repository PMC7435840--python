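"""Synthetic NIR study and HPLC observation generator.

This module emulates the data a tablet-screening study produces, so the whole
pipeline can be exercised and validated without an instrument:

* diffuse-reflectance NIR spectra (900-1700 nm, pseudo-absorbance) of
  artemether-lumefantrine tablets from seven products — two of them the same
  brand name sold through the licit and the illicit channel — with
  brand-specific excipient signatures, shared API bands, batch and tablet
  composition variability, multiplicative/additive scatter and wavelength-
  dependent detector noise (noisier outside the 1085-1601 nm core window);
* HPLC peak areas for a 3-day x 3-level x 3-replicate accuracy-profile
  validation design with duplicate daily calibration standards at the 100%
  level;
* tablet assay areas following the two-dilution sample preparation
  (1:2 for artemether, 1:100 for lumefantrine).

Every generator takes an explicit integer seed and is bit-reproducible.
Component spectra are sums of Gaussian absorption bands; this is a spectral
shape model, not a radiative-transfer model of a tablet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import SpectraSet

GRID_LOW_NM = 900.0
GRID_HIGH_NM = 1700.0
#: core analysis window; detector noise is larger outside it
CORE_WINDOW_NM = (1085.0, 1601.0)

ARTEMETHER = "artemether"
LUMEFANTRINE = "lumefantrine"


# --------------------------------------------------------------------- types
@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band: center (nm), width (SD, nm), amplitude."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if not (self.width > 0):
            raise ValueError("band width must be > 0")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be >= 0")
        if not (GRID_LOW_NM <= self.center <= GRID_HIGH_NM):
            raise ValueError(f"band center {self.center} outside [{GRID_LOW_NM}, {GRID_HIGH_NM}] nm")


@dataclass(frozen=True)
class ComponentSpectrum:
    """A pure component (API or excipient) as a sum of Gaussian bands."""

    name: str
    bands: tuple[BandSpec, ...]
    is_api: bool = False

    def __post_init__(self) -> None:
        if len(self.bands) == 0:
            raise ValueError(f"component {self.name!r} must have at least one band")


@dataclass(frozen=True)
class FormulationSpec:
    """Mass-fraction composition of one product."""

    brand: str
    component_weights: dict[str, float]
    is_falsified: bool = False

    def validate(self, library: dict[str, ComponentSpectrum]) -> None:
        total = sum(self.component_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.brand}: weights sum to {total}, not 1")
        if any(w < 0 for w in self.component_weights.values()):
            raise ValueError(f"{self.brand}: negative component weight")
        if self.is_falsified:
            for name, w in self.component_weights.items():
                if name in library and library[name].is_api and w != 0:
                    raise ValueError(f"{self.brand}: falsified product contains API {name!r}")


@dataclass(frozen=True)
class DesignRow:
    brand: str
    channel: str  # "licit" | "illicit"
    n_batches: int
    tablets_per_batch: int = 10

    def __post_init__(self) -> None:
        if self.n_batches < 1 or self.tablets_per_batch < 1:
            raise ValueError("batch and tablet counts must be >= 1")


@dataclass(frozen=True)
class StudyDesign:
    rows: tuple[DesignRow, ...]

    @property
    def n_spectra(self) -> int:
        return sum(r.n_batches * r.tablets_per_batch for r in self.rows)

    @property
    def n_batches(self) -> int:
        return sum(r.n_batches for r in self.rows)


@dataclass(frozen=True)
class NoiseModel:
    """Variability knobs of the spectral generator (all relative SDs >= 0)."""

    sigma_batch: float = 0.005     # per-batch lognormal weight perturbation
    sigma_tablet: float = 0.01     # per-tablet lognormal weight perturbation
    scatter_mult_sd: float = 0.05  # SD of log multiplicative scatter gain
    scatter_add_sd: float = 0.02   # SD of additive scatter offset
    sigma_core: float = 1e-3       # additive noise SD inside the core window
    sigma_edge: float = 5e-3       # additive noise SD outside the core window
    core_window_nm: tuple[float, float] = CORE_WINDOW_NM

    def __post_init__(self) -> None:
        for name in ("sigma_batch", "sigma_tablet", "scatter_mult_sd",
                     "scatter_add_sd", "sigma_core", "sigma_edge"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sigma_edge < self.sigma_core:
            raise ValueError("sigma_edge must be >= sigma_core")


@dataclass(frozen=True)
class ValidationTruth:
    """Ground truth for the accuracy-profile validation generator.

    ``levels`` maps the percentage level label (80/100/120) to the nominal
    concentration in mg/mL; relative bias/SDs are fractions of the nominal.
    """

    compound: str
    true_response_factor: float               # peak area per (mg/mL)
    levels: dict[int, float]
    relative_bias_per_level: dict[int, float]
    sigma_day: float = 0.02
    sigma_rep: float = 0.015
    p: int = 3                                # days
    n: int = 3                                # replicates per day per level
    n_calibration_replicates: int = 2
    calibration_level: int = 100

    def __post_init__(self) -> None:
        if self.p < 2 or self.n < 2:
            raise ValueError("need p >= 2 days and n >= 2 replicates")
        if any(c <= 0 for c in self.levels.values()):
            raise ValueError("nominal concentrations must be > 0")
        if self.calibration_level not in self.levels:
            raise ValueError("calibration level missing from levels")


# ----------------------------------------------------------------- library
def build_component_library() -> dict[str, ComponentSpectrum]:
    """Fixed, deterministic library of pure-component NIR signatures.

    Two APIs (artemether, lumefantrine) and nine excipients, each a sum of
    2-4 Gaussian overtone-like bands on 900-1700 nm.  Band positions are
    stylised, chosen so distinct components have distinct second-derivative
    signatures; the disintegrant (crospovidone) and the pigment carry narrow
    bands on purpose, as crystalline minor components tend to.
    """
    def comp(name, bands, api=False):
        return ComponentSpectrum(name, tuple(BandSpec(*b) for b in bands), is_api=api)

    # Amplitudes run roughly inverse to each component's typical mass
    # fraction, so minor crystalline components (disintegrant, lubricant,
    # glidant) show strong narrow bands while bulk fillers show broad weak
    # ones; every component then perturbs a tablet spectrum by a comparable
    # amount per unit relative weight change.
    components = [
        comp(ARTEMETHER, [(1175, 22, 1.30), (1390, 28, 0.95), (1655, 35, 0.59)], api=True),
        comp(LUMEFANTRINE, [(1135, 20, 0.24), (1300, 25, 0.19), (1520, 30, 0.15), (1670, 40, 0.10)], api=True),
        comp("cellulose", [(935, 40, 0.08), (1212, 45, 0.21), (1490, 55, 0.24)]),
        comp("lactose", [(1250, 40, 0.27), (1440, 35, 0.23), (1590, 45, 0.18)]),
        comp("starch", [(1160, 50, 0.16), (1460, 50, 0.20), (1565, 40, 0.09)]),
        comp("hypromellose", [(1100, 30, 3.00), (1370, 35, 3.60)]),
        comp("crospovidone", [(1242, 14, 0.94), (1502, 16, 1.10), (1645, 18, 0.63)]),
        comp("povidone", [(1195, 25, 2.50), (1425, 30, 2.75)]),
        comp("talc", [(1395, 15, 3.40), (1540, 18, 1.89)]),
        comp("magnesium_stearate", [(1190, 30, 2.40), (1415, 25, 1.60), (1695, 45, 3.20)]),
        comp("pigment", [(980, 25, 0.37), (1325, 18, 0.42), (1615, 22, 0.28)]),
    ]
    return {c.name: c for c in components}


def evaluate_component(component: ComponentSpectrum, grid: np.ndarray) -> np.ndarray:
    """Evaluate a component's Gaussian-band sum on a strictly increasing grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be one-dimensional and strictly increasing")
    out = np.zeros_like(grid)
    for band in component.bands:
        out += band.amplitude * np.exp(-((grid - band.center) ** 2) / (2.0 * band.width**2))
    return out


def default_grid(n_points: int = 228) -> np.ndarray:
    """Instrument-typical grid: evenly spaced points over 900-1700 nm."""
    return np.linspace(GRID_LOW_NM, GRID_HIGH_NM, n_points)


# ------------------------------------------------------------- formulations
#: API mass fractions of a 20/120 mg fixed-dose tablet of ~480 mg total mass
API_WEIGHTS = {ARTEMETHER: 1.0 / 24.0, LUMEFANTRINE: 0.25}


def _licit(brand: str, excipients: dict[str, float]) -> FormulationSpec:
    weights = dict(API_WEIGHTS)
    weights.update(excipients)
    filler = 1.0 - sum(weights.values())
    if filler < 0:
        raise ValueError(f"{brand}: excipient weights exceed available mass")
    weights["starch"] = weights.get("starch", 0.0) + filler
    return FormulationSpec(brand=brand, component_weights=weights)


def default_formulations() -> dict[tuple[str, str], FormulationSpec]:
    """Compositions of the seven products, keyed by (brand, channel).

    Licit products share the API fractions and differ mainly in their minor
    narrow-band excipients (binder/disintegrant/glidant), which dominate the
    second-derivative signatures; AL Ipca and Artefan dispersible are
    deliberately near-identical, differing only in the binder fraction.  The
    illicit-channel Combiart carries no API at
    all: its mass is starch plus a pigment standing in for the colourant a
    falsifier uses to imitate the yellow of lumefantrine.
    """
    forms: dict[tuple[str, str], FormulationSpec] = {
        ("Combiart", "licit"): _licit(
            "Combiart",
            {"cellulose": 0.40, "lactose": 0.08, "hypromellose": 0.12,
             "talc": 0.010, "magnesium_stearate": 0.008},
        ),
        ("Komefan", "licit"): _licit(
            "Komefan",
            {"lactose": 0.40, "cellulose": 0.08, "crospovidone": 0.12,
             "talc": 0.012, "magnesium_stearate": 0.008},
        ),
        ("AL Macleods", "licit"): _licit(
            "AL Macleods",
            {"starch": 0.45, "cellulose": 0.06, "povidone": 0.10,
             "talc": 0.010, "magnesium_stearate": 0.010},
        ),
        ("Artefan", "licit"): _licit(
            "Artefan",
            {"cellulose": 0.15, "lactose": 0.25, "hypromellose": 0.05,
             "povidone": 0.05, "magnesium_stearate": 0.010},
        ),
        ("Artefan dispersible", "licit"): _licit(
            "Artefan dispersible",
            {"cellulose": 0.26, "lactose": 0.18, "crospovidone": 0.06,
             "hypromellose": 0.06, "talc": 0.010, "magnesium_stearate": 0.008},
        ),
        ("AL Ipca", "licit"): _licit(
            "AL Ipca",
            {"cellulose": 0.26, "lactose": 0.18, "crospovidone": 0.06,
             "hypromellose": 0.01, "talc": 0.010, "magnesium_stearate": 0.008},
        ),
        ("Combiart", "illicit"): FormulationSpec(
            brand="Combiart",
            component_weights={ARTEMETHER: 0.0, LUMEFANTRINE: 0.0,
                               "starch": 0.80, "pigment": 0.15, "talc": 0.05},
            is_falsified=True,
        ),
    }
    library = build_component_library()
    for spec in forms.values():
        spec.validate(library)
    return forms


def default_study_design(tablets_per_batch: int = 10) -> StudyDesign:
    """Seven products, 27 batches, ten tablets per batch -> 270 spectra."""
    rows = [
        DesignRow("AL Ipca", "licit", 2, tablets_per_batch),
        DesignRow("AL Macleods", "licit", 5, tablets_per_batch),
        DesignRow("Artefan", "licit", 2, tablets_per_batch),
        DesignRow("Artefan dispersible", "licit", 4, tablets_per_batch),
        DesignRow("Combiart", "licit", 6, tablets_per_batch),
        DesignRow("Combiart", "illicit", 3, tablets_per_batch),
        DesignRow("Komefan", "licit", 5, tablets_per_batch),
    ]
    return StudyDesign(tuple(rows))


# --------------------------------------------------------------- simulation
def simulate_study(
    design: StudyDesign | None = None,
    formulations: dict[tuple[str, str], FormulationSpec] | None = None,
    noise: NoiseModel | None = None,
    grid: np.ndarray | None = None,
    seed: int = 0,
    library: dict[str, ComponentSpectrum] | None = None,
) -> SpectraSet:
    """Simulate one spectrum per (product, batch, tablet) of the design.

    Each spectrum is ``gain * sum_c w_c * component_c(grid) + offset + noise``
    where the formulation weights receive a per-batch then per-tablet
    lognormal perturbation, the scatter gain/offset vary per tablet, and the
    additive noise SD is ``sigma_edge`` outside the core window.
    """
    design = design or default_study_design()
    formulations = formulations or default_formulations()
    noise = noise or NoiseModel()
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    library = library or build_component_library()

    for row in design.rows:
        if (row.brand, row.channel) not in formulations:
            raise KeyError(f"no formulation for {(row.brand, row.channel)}")

    rng = np.random.default_rng(seed)
    lo, hi = noise.core_window_nm
    noise_sd = np.where((grid >= lo) & (grid <= hi), noise.sigma_core, noise.sigma_edge)

    all_values, meta_rows = [], []
    batch_counter = 0
    for row in design.rows:
        form = formulations[(row.brand, row.channel)]
        names = list(form.component_weights)
        base_w = np.array([form.component_weights[n] for n in names])
        comps = np.stack([evaluate_component(library[n], grid) for n in names])
        for b in range(1, row.n_batches + 1):
            batch_counter += 1
            batch_f = np.exp(rng.normal(0.0, noise.sigma_batch, size=len(names)))
            for t in range(1, row.tablets_per_batch + 1):
                tablet_f = np.exp(rng.normal(0.0, noise.sigma_tablet, size=len(names)))
                w = base_w * batch_f * tablet_f
                gain = math.exp(rng.normal(0.0, noise.scatter_mult_sd))
                offset = rng.normal(0.0, noise.scatter_add_sd)
                eps = rng.normal(0.0, 1.0, size=grid.size) * noise_sd
                all_values.append(gain * (w @ comps) + offset + eps)
                meta_rows.append(
                    {
                        "sample_id": f"{row.brand}_{row.channel}_b{batch_counter:02d}_t{t:02d}",
                        "brand": row.brand,
                        "channel": row.channel,
                        "batch": batch_counter,
                        "tablet": t,
                    }
                )
    return SpectraSet(grid, np.vstack(all_values), pd.DataFrame(meta_rows))


# ----------------------------------------------------- HPLC-side generators
DEFAULT_RESPONSE_FACTORS = {ARTEMETHER: 2000.0, LUMEFANTRINE: 160000.0}

DEFAULT_LEVELS = {
    ARTEMETHER: {80: 0.08, 100: 0.10, 120: 0.12},
    LUMEFANTRINE: {80: 0.0096, 100: 0.0120, 120: 0.0144},
}

#: generator-default trueness: small positive bias at the 80% level only
DEFAULT_BIAS = {80: 0.02, 100: 0.0, 120: 0.0}


def default_validation_truth(compound: str) -> ValidationTruth:
    if compound not in DEFAULT_LEVELS:
        raise KeyError(f"unknown compound {compound!r}")
    return ValidationTruth(
        compound=compound,
        true_response_factor=DEFAULT_RESPONSE_FACTORS[compound],
        levels=dict(DEFAULT_LEVELS[compound]),
        relative_bias_per_level=dict(DEFAULT_BIAS),
    )


def simulate_validation_areas(
    truth: ValidationTruth, compound: str | None = None, seed: int = 0
) -> pd.DataFrame:
    """Simulate the p-day x n-replicate x level validation area table.

    ``area_jk = F * conc_L * (1 + bias_L) * (1 + gamma_j) * (1 + eps_jk)``
    with a shared per-day effect ``gamma_j`` and i.i.d. replicate noise.
    Duplicate matrix-free calibration standards (bias 0) at the 100% level
    are emitted per day under ``role == "calibration"``; they carry the same
    day effect, which is what per-day calibration subsequently removes.
    """
    compound = compound or truth.compound
    for lvl in truth.relative_bias_per_level:
        if lvl not in truth.levels:
            raise KeyError(f"bias specified for unknown level {lvl!r}")
    rng = np.random.default_rng(seed)
    gamma = rng.normal(0.0, truth.sigma_day, size=truth.p)
    rows = []
    for j in range(truth.p):
        c100 = truth.levels[truth.calibration_level]
        for r in range(1, truth.n_calibration_replicates + 1):
            eps = rng.normal(0.0, truth.sigma_rep)
            rows.append(
                {
                    "day": j + 1,
                    "level": truth.calibration_level,
                    "replicate": r,
                    "compound": compound,
                    "role": "calibration",
                    "nominal_mgml": c100,
                    "area": truth.true_response_factor * c100 * (1 + gamma[j]) * (1 + eps),
                }
            )
        for level, conc in truth.levels.items():
            bias = truth.relative_bias_per_level.get(level, 0.0)
            for r in range(1, truth.n + 1):
                eps = rng.normal(0.0, truth.sigma_rep)
                rows.append(
                    {
                        "day": j + 1,
                        "level": level,
                        "replicate": r,
                        "compound": compound,
                        "role": "validation",
                        "nominal_mgml": conc,
                        "area": truth.true_response_factor
                        * conc * (1 + bias) * (1 + gamma[j]) * (1 + eps),
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AssayScheme:
    """Two-dilution tablet assay sample preparation.

    The powdered-tablet stock targets 0.2 mg/mL artemether / 1.2 mg/mL
    lumefantrine; a 1:2 dilution gives the artemether working solution
    (0.1 mg/mL nominal) and a 1:100 dilution the lumefantrine one
    (0.012 mg/mL nominal).
    """

    stock_nominal_mgml: dict[str, float] = field(
        default_factory=lambda: {ARTEMETHER: 0.2, LUMEFANTRINE: 1.2}
    )
    dilution_factor: dict[str, float] = field(
        default_factory=lambda: {ARTEMETHER: 2.0, LUMEFANTRINE: 100.0}
    )

    def injected_nominal(self, compound: str) -> float:
        return self.stock_nominal_mgml[compound] / self.dilution_factor[compound]


def simulate_assay(
    content_fraction: float | dict[str, float],
    seed: int = 0,
    response_factors: dict[str, float] | None = None,
    scheme: AssayScheme | None = None,
    sigma_rep: float = 0.01,
    baseline_sd: float = 0.05,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Simulate assay peak areas for one batch at a given content level.

    ``content_fraction`` is the true content as a fraction of the label claim
    (scalar, or per-compound dict); 0 models a falsified batch whose areas
    are pure baseline noise.
    """
    response_factors = response_factors or DEFAULT_RESPONSE_FACTORS
    scheme = scheme or AssayScheme()
    if np.isscalar(content_fraction):
        content = {c: float(content_fraction) for c in scheme.stock_nominal_mgml}
    else:
        content = dict(content_fraction)
    if any(v < 0 for v in content.values()):
        raise ValueError("content_fraction must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for compound in scheme.stock_nominal_mgml:
        conc = scheme.injected_nominal(compound) * content[compound]
        for r in range(1, n_replicates + 1):
            area = (
                response_factors[compound] * conc * (1 + rng.normal(0.0, sigma_rep))
                + rng.normal(0.0, baseline_sd)
            )
            rows.append(
                {
                    "compound": compound,
                    "replicate": r,
                    "dilution": scheme.dilution_factor[compound],
                    "area": area,
                }
            )
    return pd.DataFrame(rows)
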