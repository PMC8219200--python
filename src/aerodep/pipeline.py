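"""Config-driven end-to-end runs.

A run generates the virtual cohort and inhalation profiles, calibrates the
deposition surrogate (or uses fixed constants), simulates every product at
the requested flows, and writes the cohort, profile, deposition, summary,
C:P, and statistics tables plus a JSON manifest that records every seed
and constant needed to reproduce the run byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .aerosol import DUAL, load_products
from .breathing import ProfileConstraints, measured_profiles, optimal_profile
from .cohort import Demographics, build_airway_tree, cohort_to_frame, generate_cohort
from .deposition import (
    RegionalTargets,
    SurrogateCalibration,
    calibrate,
    results_to_frame,
    simulate_cohort,
)
from .errors import AerodepError, ConfigurationError
from .metrics import cohort_product_cp, summaries_to_frame, summarize
from .stats import equivalence_report, equivalence_to_frame, ratios_to_frame

log = logging.getLogger("aerodep")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one pipeline run."""

    n_patients: int = 20
    cohort_seed: int = 1
    profile_seed: int = 1
    demographics: Demographics = field(default_factory=Demographics)
    profile_constraints: ProfileConstraints = field(default_factory=ProfileConstraints)
    products_path: str | None = None  # None: packaged defaults
    flows: tuple[str, ...] = ("optimal", "measured")
    optimal_duration: float = 4.5
    optimal_mean_flow: float = 30.0
    calibration_mode: str = "fit-on-reference"  # or "fixed"
    reference_product: str = DUAL
    reference_targets: RegionalTargets = field(default_factory=RegionalTargets)
    fixed_calibration: SurrogateCalibration = field(default_factory=SurrogateCalibration)
    n_bins: int = 40
    cp_method: str = "arithmetic"

    def __post_init__(self) -> None:
        if self.calibration_mode not in ("fixed", "fit-on-reference"):
            raise ConfigurationError(f"unknown calibration mode {self.calibration_mode!r}")
        bad = set(self.flows) - {"optimal", "measured"}
        if bad:
            raise ConfigurationError(f"unknown flow kinds {sorted(bad)}")
        if not isinstance(self.cohort_seed, int) or not isinstance(self.profile_seed, int):
            raise ConfigurationError("seeds must be integers")


def _nested(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"{cls.__name__}: unknown keys {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML file plus keyword overrides."""
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("run config must be a YAML mapping")
        data.update(raw)
    data.update({k: v for k, v in overrides.items() if v is not None})
    for key, cls in (
        ("demographics", Demographics),
        ("profile_constraints", ProfileConstraints),
        ("reference_targets", RegionalTargets),
        ("fixed_calibration", SurrogateCalibration),
    ):
        if key in data and isinstance(data[key], dict):
            data[key] = _nested(cls, data[key])
    if "flows" in data:
        data["flows"] = tuple(data["flows"])
    return _nested(RunConfig, data)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline; returns the manifest dict.

    Writes cohort.csv, profiles.csv, deposition.csv, regional_summary.csv,
    cp_summary.csv, ratio_table.csv, equivalence_table.csv, and
    manifest.json under ``out_dir``.  Outputs are deterministic for a
    fixed config; partial outputs are removed if the run fails.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        log.info("generating cohort (n=%d, seed=%d)", config.n_patients, config.cohort_seed)
        patients = generate_cohort(config.n_patients, config.demographics, config.cohort_seed)
        trees = [build_airway_tree(p) for p in patients]
        products = load_products(config.products_path)
        if config.reference_product not in products:
            raise ConfigurationError(
                f"reference product {config.reference_product!r} not among {sorted(products)}"
            )

        profile_sets: dict[str, list] = {}
        if "optimal" in config.flows:
            profile_sets["optimal"] = [
                optimal_profile(config.optimal_duration, config.optimal_mean_flow)
            ] * config.n_patients
        if "measured" in config.flows:
            profile_sets["measured"] = measured_profiles(
                config.n_patients, config.profile_constraints, config.profile_seed
            )

        if config.calibration_mode == "fit-on-reference":
            fit_profiles = profile_sets.get("measured") or next(iter(profile_sets.values()))
            log.info("calibrating on %s", config.reference_product)
            calres = calibrate(
                products[config.reference_product],
                config.reference_targets,
                patients,
                fit_profiles,
                trees=trees,
                n_bins=config.n_bins,
            )
            calib = calres.calibration
            cal_info = {
                "mode": config.calibration_mode,
                "reference_product": config.reference_product,
                "constants": dataclasses.asdict(calib),
                "residuals": calres.residuals,
                "achieved": calres.achieved,
            }
        else:
            calib = config.fixed_calibration
            cal_info = {"mode": "fixed", "constants": dataclasses.asdict(calib)}

        results = []
        for flow, profiles in profile_sets.items():
            for product in products.values():
                log.info("simulating %s at %s flow", product.name, flow)
                results.extend(
                    simulate_cohort(patients, trees, product, profiles, calib, config.n_bins)
                )
        table = results_to_frame(results)

        cohort_df = cohort_to_frame(patients)
        prof_rows = []
        for flow, profiles in profile_sets.items():
            for p, prof in zip(patients, profiles):
                prof_rows.append(
                    {
                        "patient_id": p.id,
                        "flow_kind": flow,
                        "duration_s": prof.duration,
                        "inhaled_volume_L": prof.inhaled_volume,
                        "mean_flow_L_min": prof.mean_flow,
                    }
                )
        profiles_df = pd.DataFrame(prof_rows)

        summary_df = summaries_to_frame(summarize(table))
        cp_df = cohort_product_cp(results, method=config.cp_method)

        stats_table = table[table["region"].isin(["intrathoracic", "central", "peripheral"])]
        stats_table = stats_table.rename(columns={"pct_nominal": "value"})[
            ["patient_id", "api", "product", "flow_kind", "region", "value"]
        ]
        equiv, ratios = equivalence_report(stats_table)

        outputs = {
            "cohort.csv": cohort_df,
            "profiles.csv": profiles_df,
            "deposition.csv": table,
            "regional_summary.csv": summary_df,
            "cp_summary.csv": cp_df,
            "ratio_table.csv": ratios_to_frame(ratios),
            "equivalence_table.csv": equivalence_to_frame(equiv),
        }
        for name, df in outputs.items():
            path = out / name
            _write_csv(df, path)
            written.append(path)

        manifest = {
            "package_version": __version__,
            "n_patients": config.n_patients,
            "seeds": {"cohort": config.cohort_seed, "profiles": config.profile_seed},
            "flows": list(config.flows),
            "products": sorted(products),
            "calibration": cal_info,
            "outputs": sorted(outputs),
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(manifest_path)
        log.info("run complete: %d files in %s", len(written), out)
        return manifest
    except AerodepError:
        for path in written:
            path.unlink(missing_ok=True)
        raise
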