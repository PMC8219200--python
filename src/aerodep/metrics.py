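"""Descriptive regional statistics and the central-to-peripheral ratio."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deposition import DepositionResult
from .errors import DomainError, UndefinedRatioError


@dataclass(frozen=True)
class RegionalSummary:
    product: str
    flow_kind: str
    region: str
    mean: float
    sd: float
    n: int
    degenerate: bool = False  # single observation: SD reported as 0


def cp_ratio(result: DepositionResult) -> float:
    """Central deposition divided by peripheral deposition for one API."""
    if result.peripheral == 0:
        raise UndefinedRatioError(
            f"{result.patient_id}/{result.product}/{result.api}: zero peripheral deposition"
        )
    return result.central / result.peripheral


def product_cp(results: list[DepositionResult], method: str = "arithmetic") -> float:
    """Product-level C:P for one patient: per-API ratios averaged.

    The average over the two or three APIs is arithmetic by default;
    a geometric mean is available via ``method="geometric"``.
    """
    if len(results) < 2:
        raise DomainError("product-level C:P needs at least 2 API results")
    ratios = [cp_ratio(r) for r in results]
    if method == "arithmetic":
        return float(np.mean(ratios))
    if method == "geometric":
        return float(np.exp(np.mean(np.log(ratios))))
    raise DomainError(f"unknown averaging method {method!r}")


def summarize(
    table: pd.DataFrame,
    by: tuple[str, ...] = ("product", "flow_kind", "region"),
    value: str = "pct_nominal",
) -> list[RegionalSummary]:
    """Group-wise mean and sample SD (n-1 denominator) of deposition.

    Groups with a single row get SD 0 and are flagged ``degenerate``;
    empty groups are dropped with a warning.
    """
    if table.empty:
        raise DomainError("cannot summarise an empty deposition table")
    out: list[RegionalSummary] = []
    for keys, grp in table.groupby(list(by), sort=True):
        vals = grp[value].to_numpy(dtype=float)
        if vals.size == 0:
            warnings.warn(f"empty group {keys} excluded from summary")
            continue
        info = dict(zip(by, keys if isinstance(keys, tuple) else (keys,)))
        out.append(
            RegionalSummary(
                product=str(info.get("product", "")),
                flow_kind=str(info.get("flow_kind", "")),
                region=str(info.get("region", "")),
                mean=float(vals.mean()),
                sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                n=int(vals.size),
                degenerate=vals.size == 1,
            )
        )
    return out


def summaries_to_frame(summaries: list[RegionalSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "product": s.product,
                "flow_kind": s.flow_kind,
                "region": s.region,
                "mean": s.mean,
                "sd": s.sd,
                "n": s.n,
                "degenerate": s.degenerate,
            }
            for s in summaries
        ]
    )


def cohort_product_cp(
    results: list[DepositionResult], method: str = "arithmetic"
) -> pd.DataFrame:
    """Per-patient product-level C:P ratios, one row per patient x flow."""
    rows = []
    grouped: dict[tuple[str, str, str], list[DepositionResult]] = {}
    for r in results:
        grouped.setdefault((r.patient_id, r.product, r.flow_kind), []).append(r)
    for (pid, product, flow), rs in sorted(grouped.items()):
        rows.append(
            {
                "patient_id": pid,
                "product": product,
                "flow_kind": flow,
                "cp_ratio": product_cp(rs, method=method),
            }
        )
    return pd.DataFrame(rows)
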