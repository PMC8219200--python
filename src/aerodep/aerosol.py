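"""Drug-delivery inputs: particle size distributions, dose accounting, plume.

The two fixed-combination pMDI products are described per active
pharmaceutical ingredient (API) by a lognormal aerodynamic particle size
distribution (MMAD, GSD), a fine particle fraction (FPF, expressed as a
fraction of the delivered dose), and a delivered dose (DD, the mass leaving
the device per actuation).  The delivered dose decomposes into

* a *fine* fraction (aerodynamic diameter at or below the FPF cut-off,
  5 um by impactor convention) that is carried by the airflow and is the
  only mass the airway deposition model transports, and
* a *coarse* / ballistic remainder that, as on the induction port of a
  cascade impactor, deposits entirely in the extrathoracic region.

The difference between nominal and delivered dose is device retention and
never enters the airways.  All deposition results downstream are expressed
as a percentage of the nominal dose, so the three components
(fine + coarse + retention) sum to one exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy import stats as sps

from .errors import ConfigurationError, DomainError

#: impactor convention for the fine-particle cut-off, um aerodynamic diameter
FPF_CUTOFF_UM = 5.0


@dataclass(frozen=True)
class ParticleSizeDistribution:
    """Binned aerosol mass distribution over aerodynamic diameter.

    ``bin_edges`` has ``n + 1`` strictly increasing entries (um);
    ``bin_mass_fractions`` has ``n`` non-negative entries summing to one.
    """

    bin_edges: np.ndarray
    bin_mass_fractions: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        mass = np.asarray(self.bin_mass_fractions, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "bin_mass_fractions", mass)
        if edges.ndim != 1 or mass.ndim != 1 or edges.size != mass.size + 1:
            raise DomainError("bin_edges must have one more entry than bin_mass_fractions")
        if np.any(np.diff(edges) <= 0):
            raise DomainError("bin_edges must be strictly increasing")
        if np.any(mass < 0):
            raise DomainError("bin mass fractions must be non-negative")
        if abs(mass.sum() - 1.0) > 1e-9:
            raise DomainError(f"bin mass fractions sum to {mass.sum()}, expected 1")

    @property
    def bin_centers(self) -> np.ndarray:
        """Geometric bin mid-points (um), the representative diameters."""
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    def mass_median(self) -> float:
        """Mass median diameter of the binned distribution (um).

        Linear interpolation of the cumulative mass on the log-diameter axis.
        """
        cum = np.concatenate([[0.0], np.cumsum(self.bin_mass_fractions)])
        return float(np.exp(np.interp(0.5, cum, np.log(self.bin_edges))))

    def cumulative_below(self, d: float) -> float:
        """Mass fraction at aerodynamic diameters <= ``d`` um."""
        cum = np.concatenate([[0.0], np.cumsum(self.bin_mass_fractions)])
        return float(np.interp(np.log(d), np.log(self.bin_edges), cum))

    def truncated(self, d_max: float) -> "ParticleSizeDistribution":
        """Restrict to diameters <= ``d_max`` and renormalise to unit mass.

        A bin straddling the cut keeps the mass share proportional to its
        log-width below the cut (mass treated as uniform in log diameter
        within a bin).
        """
        edges = self.bin_edges
        if d_max <= edges[0]:
            raise ConfigurationError(f"truncation at {d_max} um removes the whole distribution")
        lo, hi = edges[:-1], edges[1:]
        frac = np.clip((np.log(d_max) - np.log(lo)) / (np.log(hi) - np.log(lo)), 0.0, 1.0)
        mass = self.bin_mass_fractions * frac
        keep = lo < d_max
        new_edges = np.concatenate([edges[:-1][keep], [min(d_max, edges[-1])]])
        new_mass = mass[keep]
        total = new_mass.sum()
        if total <= 0:
            raise ConfigurationError("no aerosol mass below the truncation diameter")
        return ParticleSizeDistribution(new_edges, new_mass / total)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "d_lo_um": self.bin_edges[:-1],
                "d_hi_um": self.bin_edges[1:],
                "d_mid_um": self.bin_centers,
                "mass_fraction": self.bin_mass_fractions,
            }
        )


def build_psd(
    mmad: float,
    gsd: float,
    n_bins: int = 40,
    d_range: tuple[float, float] = (0.1, 20.0),
) -> ParticleSizeDistribution:
    """Binned lognormal mass distribution from impactor MMAD and GSD.

    The aerosol mass is lognormally distributed over aerodynamic diameter
    with median ``mmad`` and geometric standard deviation ``gsd``; the
    probability mass falling in each of ``n_bins`` log-spaced bins across
    ``d_range`` is renormalised to one.  A GSD of exactly 1 (monodisperse)
    is nudged to ``1 + 1e-9`` so the lognormal remains defined.
    """
    if gsd < 1.0:
        raise DomainError(f"GSD must be >= 1, got {gsd}")
    if n_bins < 1:
        raise DomainError("n_bins must be >= 1")
    d_lo, d_hi = d_range
    if not (0 < d_lo < mmad < d_hi):
        raise ConfigurationError(f"diameter range {d_range} um must span the MMAD {mmad} um")
    sigma = np.log(max(gsd, 1.0 + 1e-9))
    edges = np.geomspace(d_lo, d_hi, n_bins + 1)
    cdf = sps.norm.cdf((np.log(edges) - np.log(mmad)) / sigma)
    mass = np.diff(cdf)
    total = mass.sum()
    if total <= 0:
        raise ConfigurationError("diameter range captures no aerosol mass")
    return ParticleSizeDistribution(edges, mass / total)


@dataclass(frozen=True)
class APIComponent:
    """One active pharmaceutical ingredient of a combination product."""

    name: str
    nominal_dose: float  # ug per actuation (label claim)
    delivered_dose: float  # ug per actuation leaving the device (DD)
    mmad: float  # um
    gsd: float
    fpf: float  # fine particle fraction, as a fraction of DD

    def __post_init__(self) -> None:
        if self.delivered_dose > self.nominal_dose:
            raise DomainError(
                f"{self.name}: delivered dose {self.delivered_dose} exceeds nominal {self.nominal_dose}"
            )
        if self.mmad <= 0 or self.gsd < 1.0:
            raise DomainError(f"{self.name}: need MMAD > 0 and GSD >= 1")
        if not (0.0 <= self.fpf <= 1.0):
            raise DomainError(f"{self.name}: FPF must lie in [0, 1], got {self.fpf}")
        if self.nominal_dose <= 0:
            raise DomainError(f"{self.name}: nominal dose must be positive")

    def fine_psd(
        self, n_bins: int = 40, d_range: tuple[float, float] = (0.05, 20.0)
    ) -> ParticleSizeDistribution:
        """PSD of the fine (sub-cut-off) aerosol that enters the airways."""
        return build_psd(self.mmad, self.gsd, n_bins=n_bins, d_range=d_range).truncated(
            FPF_CUTOFF_UM
        )


def dose_decomposition(api: APIComponent) -> tuple[float, float]:
    """Split the nominal dose into coarse and fine airborne fractions.

    Returns ``(coarse_frac_nominal, fine_frac_nominal)``.  Together with the
    device retention ``1 - DD/nominal`` the parts sum to one exactly.
    """
    dd_frac = api.delivered_dose / api.nominal_dose
    fine = api.fpf * dd_frac
    coarse = (1.0 - api.fpf) * dd_frac
    return coarse, fine


def device_retention(api: APIComponent) -> float:
    return 1.0 - api.delivered_dose / api.nominal_dose


@dataclass(frozen=True)
class PlumeCharacteristics:
    """Measured pMDI spray plume properties.

    ``shot_mass`` and ``cone_angle`` are carried for reporting but do not
    enter the deposition surrogate; the surrogate uses the 100 mm ejection
    velocity (throat distance) as its plume-momentum input.
    """

    shot_mass: float  # g
    cone_angle: float  # degrees
    velocity_10mm: float  # m/s just after actuator exit
    velocity_100mm: float  # m/s at throat distance
    duration: float  # ms

    def __post_init__(self) -> None:
        for name in ("shot_mass", "cone_angle", "velocity_10mm", "velocity_100mm", "duration"):
            if getattr(self, name) <= 0:
                raise DomainError(f"plume {name} must be positive")
        if self.velocity_100mm > self.velocity_10mm:
            raise DomainError("plume velocity at 100 mm cannot exceed velocity at 10 mm")


@dataclass(frozen=True)
class Product:
    """A fixed-combination pMDI: two or three APIs sharing one plume."""

    name: str
    apis: tuple[APIComponent, ...]
    plume: PlumeCharacteristics

    def __post_init__(self) -> None:
        object.__setattr__(self, "apis", tuple(self.apis))
        if not 2 <= len(self.apis) <= 3:
            raise DomainError(f"{self.name}: a combination product carries 2 or 3 APIs")

    def api(self, name: str) -> APIComponent:
        for a in self.apis:
            if a.name == name:
                return a
        raise KeyError(f"{self.name} has no API named {name!r}")


def _product_from_dict(name: str, spec: dict) -> Product:
    p = spec["plume"]
    plume = PlumeCharacteristics(
        shot_mass=p["shot_mass_g"],
        cone_angle=p["cone_angle_deg"],
        velocity_10mm=p["velocity_10mm_m_s"],
        velocity_100mm=p["velocity_100mm_m_s"],
        duration=p["duration_ms"],
    )
    apis = tuple(
        APIComponent(
            name=a["name"],
            nominal_dose=a["nominal_dose_ug"],
            delivered_dose=a["delivered_dose_ug"],
            mmad=a["mmad_um"],
            gsd=a["gsd"],
            fpf=a["fpf"],
        )
        for a in spec["apis"]
    )
    return Product(name=name, apis=apis, plume=plume)


def load_products(path: str | Path | None = None) -> dict[str, Product]:
    """Load product definitions from YAML (the packaged file by default).

    The shipped default transcribes the measured plume and particle
    characteristics of the extrafine triple (BDP/FF/GB) and dual (BDP/FF)
    combination pMDIs.
    """
    if path is None:
        text = resources.files("aerodep.data").joinpath("products.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "products" not in raw:
        raise ConfigurationError("product config must contain a top-level 'products' mapping")
    return {name: _product_from_dict(name, spec) for name, spec in raw["products"].items()}


def default_products() -> dict[str, Product]:
    return load_products(None)


TRIPLE = "BDP/FF/GB"
DUAL = "BDP/FF"
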