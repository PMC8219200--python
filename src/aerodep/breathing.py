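"""Inhalation flow profiles: idealised and real-life (measured-style).

Two waveform families drive the deposition model.  The *optimal* profile is
the slow deep inhalation recommended for pMDI use: 4-5 s duration at a mean
flow of ~30 L/min.  *Measured* profiles emulate real-life COPD inhalations:
per-patient inspiratory volume and time are sampled from lognormal
distributions and the resulting mean flows are affinely rescaled so the
cohort mean hits the configured target exactly while every profile stays
inside the admissible flow range.

Both use a half-sine waveform (single-peaked, smooth, zero at the ends),
so peak flow = pi/2 x mean flow.  Exhalation is not modelled: the
deposition closure assumes no particle is exhaled.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DomainError, InvalidCohortError

_DT = 0.01  # s, waveform sampling step


@dataclass(frozen=True)
class ProfileConstraints:
    """Targets and sampling distributions for measured-style profiles."""

    mean_flow_target: float = 29.35  # L/min, cohort mean (hit exactly)
    flow_min: float = 16.15  # L/min, admissible range of per-profile means
    flow_max: float = 68.83
    volume_median: float = 1.5  # L, lognormal median of inspiratory volume
    volume_gsd: float = 1.35
    time_median: float = 3.0  # s, lognormal median of inspiratory time
    time_gsd: float = 1.25
    time_bounds: tuple[float, float] = (1.5, 6.0)

    def __post_init__(self) -> None:
        if not (self.flow_min < self.mean_flow_target < self.flow_max):
            raise ConfigurationError(
                f"target mean flow {self.mean_flow_target} outside admissible range "
                f"[{self.flow_min}, {self.flow_max}]"
            )
        if self.volume_median <= 0 or self.time_median <= 0:
            raise ConfigurationError("lognormal medians must be positive")
        if self.volume_gsd < 1 or self.time_gsd < 1:
            raise ConfigurationError("lognormal GSDs must be >= 1")


@dataclass(frozen=True)
class InhalationProfile:
    """Time-resolved inspiratory flow waveform on a uniform grid."""

    kind: str  # {"optimal", "measured"}
    times: np.ndarray  # s
    flows: np.ndarray  # L/min, non-negative
    duration: float  # s
    inhaled_volume: float  # L
    mean_flow: float  # L/min

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        q = np.asarray(self.flows, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "flows", q)
        if np.any(q < 0):
            raise DomainError("flows must be non-negative")
        vol = np.trapezoid(q / 60.0, t)  # L
        if abs(vol - self.inhaled_volume) > 0.005 * self.inhaled_volume:
            raise DomainError(
                f"waveform integrates to {vol:.4f} L, inconsistent with "
                f"declared inhaled volume {self.inhaled_volume:.4f} L"
            )
        if abs(self.mean_flow - self.inhaled_volume / self.duration * 60.0) > 1e-6 * max(
            1.0, self.mean_flow
        ):
            raise DomainError("mean_flow inconsistent with inhaled_volume / duration")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_s": self.times, "flow_L_min": self.flows})


def _half_sine(kind: str, duration: float, mean_flow: float) -> InhalationProfile:
    n = max(int(round(duration / _DT)), 20)
    t = np.linspace(0.0, duration, n + 1)
    peak = (np.pi / 2.0) * mean_flow
    q = np.maximum(peak * np.sin(np.pi * t / duration), 0.0)
    return InhalationProfile(
        kind=kind,
        times=t,
        flows=q,
        duration=duration,
        inhaled_volume=mean_flow / 60.0 * duration,
        mean_flow=mean_flow,
    )


def optimal_profile(duration: float = 4.5, target_mean_flow: float = 30.0) -> InhalationProfile:
    """Idealised slow-and-deep pMDI inhalation.

    Half-sine waveform whose mean flow equals ``target_mean_flow`` exactly
    (peak = pi/2 x mean).  Default 4.5 s at 30 L/min inhales 2.25 L.
    """
    if duration <= 0 or target_mean_flow <= 0:
        raise DomainError("duration and target mean flow must be positive")
    return _half_sine("optimal", duration, target_mean_flow)


def measured_profiles(
    n: int,
    constraints: ProfileConstraints | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> list[InhalationProfile]:
    """Sample ``n`` real-life-style inhalation profiles.

    Per profile, inspiratory volume and time are drawn from lognormal
    distributions; the implied mean flows are then shrunk affinely about
    the target so the cohort mean equals ``mean_flow_target`` exactly and
    every profile's mean flow lies inside ``[flow_min, flow_max]``.  The
    sampled inspiratory time is kept; the volume is adjusted to match the
    rescaled flow.
    """
    if n < 2:
        raise InvalidCohortError(f"need at least 2 profiles, got {n}")
    c = constraints or ProfileConstraints()
    rng = np.random.default_rng(seed)
    vol = c.volume_median * np.exp(np.log(c.volume_gsd) * rng.standard_normal(n))
    t_in = c.time_median * np.exp(np.log(c.time_gsd) * rng.standard_normal(n))
    t_in = np.clip(t_in, *c.time_bounds)
    q = vol / t_in * 60.0  # L/min

    # Shrink towards the target mean until the whole cohort fits the range.
    dev = q - q.mean()
    scale = 1.0
    lo_dev, hi_dev = dev.min(), dev.max()
    if lo_dev < 0:
        scale = min(scale, 0.999 * (c.mean_flow_target - c.flow_min) / -lo_dev)
    if hi_dev > 0:
        scale = min(scale, 0.999 * (c.flow_max - c.mean_flow_target) / hi_dev)
    q_scaled = c.mean_flow_target + scale * dev

    profiles = [_half_sine("measured", float(ti), float(qi)) for ti, qi in zip(t_in, q_scaled)]
    return profiles
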