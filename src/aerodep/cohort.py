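"""Virtual COPD cohort: demographics, lobar volumes, and airway geometry.

The study population this generator emulates is a 20-patient cohort with
moderate-to-severe airflow obstruction (15 M / 5 F; age 64.0 +/- 7.68 y;
height 168.9 +/- 8.40 cm; post-bronchodilator FEV1 42.3 +/- 14.8 %
predicted).  Real studies of this kind derive, from paired
inspiratory/expiratory HRCT scans, per-lobe volumes at total lung capacity
(TLC) and functional residual capacity (FRC) plus a patient-specific 3D
airway model down to the ~1-2 mm diameter resolution limit.  Here both are
synthesised:

* demographics are truncated-normal draws affinely rescaled so the cohort
  sample means hit the configured targets exactly;
* lung volumes follow standard height/sex TLC prediction equations with a
  hyperinflation factor, and an FRC/TLC ratio that worsens (rises) as FEV1
  falls;
* lobar inspiratory volumes follow fixed physiological proportions with
  per-patient jitter, and lobar expansion (inspiration minus expiration,
  assumed uniform within a lobe) sets each lobe's share of inspired flow;
* the airway tree is a published-style symmetric 24-generation morphometry
  table, isotropically rescaled to the patient's TLC by a cube-root volume
  factor, with an FEV1-dependent narrowing factor applied to the airways
  distal to the central cut-off (HRCT-resolvable limit, default 2 mm
  diameter).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateLobeError, InvalidCohortError

LOBE_LABELS = ("RUL", "RML", "RLL", "LUL", "LLL")

#: default lobar shares of the inspiratory (TLC) volume
_LOBE_INSP_FRACTIONS = {"RUL": 0.20, "RML": 0.09, "RLL": 0.25, "LUL": 0.21, "LLL": 0.25}

#: lung volume of the reference morphometry table, litres
REFERENCE_VOLUME_L = 4.8

#: HRCT-resolvable airway diameter, cm: central/peripheral partition
DEFAULT_CENTRAL_CUTOFF_CM = 0.2


@dataclass(frozen=True)
class LungLobe:
    label: str
    vol_exp: float  # L at expiration (FRC scan)
    vol_insp: float  # L at inspiration (TLC scan)

    def __post_init__(self) -> None:
        if not (self.vol_insp > self.vol_exp > 0):
            raise DegenerateLobeError(
                f"lobe {self.label}: need vol_insp > vol_exp > 0, "
                f"got insp={self.vol_insp}, exp={self.vol_exp}"
            )

    @property
    def expansion(self) -> float:
        return self.vol_insp - self.vol_exp


@dataclass(frozen=True)
class Patient:
    id: str
    sex: str  # {"M", "F"}
    age: float  # years
    height: float  # cm
    fev1_pct_pred: float
    tlc: float  # L, inspiratory scan volume
    frc: float  # L, expiratory scan volume
    lobes: tuple[LungLobe, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "lobes", tuple(self.lobes))
        if self.sex not in ("M", "F"):
            raise InvalidCohortError(f"sex must be M or F, got {self.sex!r}")
        if not (self.tlc > self.frc > 0):
            raise InvalidCohortError(f"{self.id}: need TLC > FRC > 0")
        si = sum(l.vol_insp for l in self.lobes)
        se = sum(l.vol_exp for l in self.lobes)
        if abs(si - self.tlc) > 1e-3 * self.tlc or abs(se - self.frc) > 1e-3 * self.frc:
            raise InvalidCohortError(f"{self.id}: lobar volumes do not sum to TLC/FRC")

    def lobe(self, label: str) -> LungLobe:
        for l in self.lobes:
            if l.label == label:
                return l
        raise KeyError(label)


@dataclass(frozen=True)
class AirwayGeneration:
    index: int
    count: float  # airways in this generation (whole lung)
    diameter: float  # cm
    length: float  # cm
    branch_angle: float  # degrees, from the parent axis
    gravity_angle: float  # degrees, airway axis to the gravity vector
    is_central: bool


@dataclass(frozen=True)
class AirwayTree:
    generations: tuple[AirwayGeneration, ...]
    scale_factor: float
    obstruction_factor: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "generations", tuple(self.generations))
        if self.scale_factor <= 0:
            raise ConfigurationError("scale_factor must be positive")
        if not (0 < self.obstruction_factor <= 1):
            raise ConfigurationError("obstruction_factor must lie in (0, 1]")

    @property
    def central_generations(self) -> tuple[AirwayGeneration, ...]:
        return tuple(g for g in self.generations if g.is_central)


@dataclass(frozen=True)
class Demographics:
    """Cohort-level targets; means are matched exactly after rescaling."""

    n_male: int = 15
    n_female: int = 5
    age_mean: float = 64.0
    age_sd: float = 7.68
    age_bounds: tuple[float, float] = (40.0, 85.0)
    height_mean: float = 168.9
    height_sd: float = 8.40
    height_bounds: tuple[float, float] = (145.0, 195.0)
    fev1_mean: float = 42.3
    fev1_sd: float = 14.8
    fev1_bounds: tuple[float, float] = (25.0, 80.0)  # moderate-to-severe band
    hyperinflation: float = 1.08  # TLC excess over predicted in COPD
    lobe_jitter_sd: float = 0.015  # SD of additive jitter on lobar fractions
    frc_ratio_jitter_sd: float = 0.03

    def __post_init__(self) -> None:
        for name in ("age", "height", "fev1"):
            mean = getattr(self, f"{name}_mean")
            sd = getattr(self, f"{name}_sd")
            lo, hi = getattr(self, f"{name}_bounds")
            if mean <= 0 or sd < 0:
                raise ConfigurationError(f"{name}: mean must be positive, SD non-negative")
            if not (lo < mean < hi):
                raise ConfigurationError(
                    f"{name}: truncation bounds ({lo}, {hi}) do not contain the mean {mean}"
                )


def _truncated_rescaled(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    bounds: tuple[float, float],
) -> np.ndarray:
    """Truncated-normal draws affinely rescaled to the exact target mean.

    The sample SD is matched before re-imposing the bounds, so the final SD
    is approximate while the mean is exact (clipping is re-centred
    iteratively).
    """
    lo, hi = bounds
    if sd == 0:
        return np.full(n, mean)
    x = rng.normal(mean, sd, size=4 * n)
    x = x[(x >= lo) & (x <= hi)]
    while x.size < n:
        extra = rng.normal(mean, sd, size=4 * n)
        x = np.concatenate([x, extra[(extra >= lo) & (extra <= hi)]])
    x = x[:n]
    s = x.std(ddof=1)
    if s > 0:
        x = mean + (x - x.mean()) * (sd / s)
    for _ in range(200):
        x = np.clip(x, lo, hi)
        delta = mean - x.mean()
        if abs(delta) < 1e-12 * max(1.0, abs(mean)):
            break
        x = x + delta
    else:
        raise ConfigurationError("could not match the target mean within the truncation bounds")
    return x


def _predicted_tlc(sex: str, height_cm: float) -> float:
    # ECSC summary equations, litres, height in metres
    h = height_cm / 100.0
    if sex == "M":
        return 7.99 * h - 7.08
    return 6.60 * h - 5.79


def generate_cohort(
    n: int = 20,
    demographics: Demographics | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> list[Patient]:
    """Draw a virtual cohort of ``n`` COPD patients.

    Sex counts follow the configured split (scaled proportionally when
    ``n`` differs from its total); age, height, and FEV1 % predicted are
    truncated-normal draws rescaled so the cohort means equal the targets
    exactly.  Lung and lobar volumes are derived per patient as described
    in the module docstring.  All randomness flows from ``seed``.
    """
    if n < 2:
        raise InvalidCohortError(f"a cohort needs at least 2 patients, got {n}")
    demo = demographics or Demographics()
    rng = np.random.default_rng(seed)

    total = demo.n_male + demo.n_female
    n_male = int(round(n * demo.n_male / total)) if n != total else demo.n_male
    n_male = min(max(n_male, 0), n)
    sexes = ["M"] * n_male + ["F"] * (n - n_male)

    age = _truncated_rescaled(rng, n, demo.age_mean, demo.age_sd, demo.age_bounds)
    height = _truncated_rescaled(rng, n, demo.height_mean, demo.height_sd, demo.height_bounds)
    fev1 = _truncated_rescaled(rng, n, demo.fev1_mean, demo.fev1_sd, demo.fev1_bounds)

    patients: list[Patient] = []
    for i in range(n):
        tlc = _predicted_tlc(sexes[i], height[i]) * demo.hyperinflation
        # air trapping: FRC/TLC rises as FEV1 falls
        ratio = 0.75 - 0.002 * fev1[i] + demo.frc_ratio_jitter_sd * rng.standard_normal()
        ratio = float(np.clip(ratio, 0.45, 0.85))
        frc = tlc * ratio

        base = np.array([_LOBE_INSP_FRACTIONS[l] for l in LOBE_LABELS])
        frac = base + demo.lobe_jitter_sd * rng.standard_normal(5)
        frac = np.clip(frac, 0.03, None)
        frac = frac / frac.sum()
        vol_insp = frac * tlc

        r = ratio * (1.0 + 0.05 * rng.standard_normal(5))
        r = np.clip(r, 0.35, 0.92)
        vol_exp = r * vol_insp
        vol_exp = vol_exp * (frc / vol_exp.sum())
        vol_exp = np.minimum(vol_exp, 0.97 * vol_insp)
        vol_exp = vol_exp * (frc / vol_exp.sum())

        lobes = tuple(
            LungLobe(label=l, vol_exp=float(e), vol_insp=float(vi))
            for l, e, vi in zip(LOBE_LABELS, vol_exp, vol_insp)
        )
        patients.append(
            Patient(
                id=f"P{i + 1:03d}",
                sex=sexes[i],
                age=float(age[i]),
                height=float(height[i]),
                fev1_pct_pred=float(fev1[i]),
                tlc=float(tlc),
                frc=float(frc),
                lobes=lobes,
            )
        )
    return patients


def lobar_expansion_fractions(patient: Patient) -> dict[str, float]:
    """Share of inspired flow directed to each lobe.

    The fraction of flow exiting toward a lobe equals that lobe's share of
    the total inspiratory-to-expiratory volume change (relative lobar
    expansion).  Fractions sum to one.
    """
    expansions = {}
    for lobe in patient.lobes:
        if lobe.vol_insp <= lobe.vol_exp:
            raise DegenerateLobeError(
                f"{patient.id}/{lobe.label}: inspiratory volume must exceed expiratory"
            )
        expansions[lobe.label] = lobe.expansion
    total = sum(expansions.values())
    return {label: e / total for label, e in expansions.items()}


def lobar_volume_fractions(patient: Patient) -> dict[str, float]:
    """Each lobe's share of the inspiratory (TLC) volume."""
    return {l.label: l.vol_insp / patient.tlc for l in patient.lobes}


def load_morphometry(path: str | Path | None = None) -> pd.DataFrame:
    """Reference airway morphometry table (symmetric, 24 generations).

    Columns: generation, count, diameter_cm, length_cm, branch_angle_deg,
    gravity_angle_deg.  Dimensions refer to a lung volume of
    ``REFERENCE_VOLUME_L`` litres.
    """
    if path is None:
        text = resources.files("aerodep.data").joinpath("morphometry.csv").read_text()
        df = pd.read_csv(io.StringIO(text))
    else:
        df = pd.read_csv(path)
    required = {
        "generation",
        "count",
        "diameter_cm",
        "length_cm",
        "branch_angle_deg",
        "gravity_angle_deg",
    }
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"morphometry table missing columns: {sorted(missing)}")
    if df["generation"].tolist() != list(range(len(df))):
        raise ConfigurationError("morphometry generations must be contiguous from 0")
    return df


def obstruction_factor(fev1_pct_pred: float) -> float:
    """Multiplicative COPD narrowing of distal airway diameters.

    Monotone non-decreasing in FEV1 % predicted and exactly 1 at or above
    100 % predicted, so an unobstructed patient reproduces the reference
    geometry.
    """
    return float(min(1.0, 0.4 + 0.6 * fev1_pct_pred / 100.0))


def build_airway_tree(
    patient: Patient,
    morphometry: pd.DataFrame | None = None,
    central_cutoff: float = DEFAULT_CENTRAL_CUTOFF_CM,
    reference_volume: float = REFERENCE_VOLUME_L,
) -> AirwayTree:
    """Scale the reference morphometry to one patient.

    Diameters and lengths scale isotropically with ``(TLC /
    reference_volume)**(1/3)``; generations whose scaled diameter falls
    below ``central_cutoff`` are peripheral and additionally narrowed by
    the patient's obstruction factor.
    """
    table = morphometry if morphometry is not None else load_morphometry()
    scale = float((patient.tlc / reference_volume) ** (1.0 / 3.0))
    obstruction = obstruction_factor(patient.fev1_pct_pred)
    gens = []
    for _, row in table.iterrows():
        d = float(row["diameter_cm"]) * scale
        is_central = d >= central_cutoff
        if not is_central:
            d *= obstruction
        gens.append(
            AirwayGeneration(
                index=int(row["generation"]),
                count=float(row["count"]),
                diameter=d,
                length=float(row["length_cm"]) * scale,
                branch_angle=float(row["branch_angle_deg"]),
                gravity_angle=float(row["gravity_angle_deg"]),
                is_central=is_central,
            )
        )
    return AirwayTree(generations=tuple(gens), scale_factor=scale, obstruction_factor=obstruction)


def cohort_to_frame(patients: list[Patient]) -> pd.DataFrame:
    """One row per patient; lobar volumes in wide columns."""
    rows = []
    for p in patients:
        row = {
            "patient_id": p.id,
            "sex": p.sex,
            "age_y": p.age,
            "height_cm": p.height,
            "fev1_pct_pred": p.fev1_pct_pred,
            "tlc_L": p.tlc,
            "frc_L": p.frc,
        }
        for lobe in p.lobes:
            row[f"{lobe.label}_insp_L"] = lobe.vol_insp
            row[f"{lobe.label}_exp_L"] = lobe.vol_exp
        rows.append(row)
    return pd.DataFrame(rows)
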