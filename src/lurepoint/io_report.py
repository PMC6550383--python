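"""Reading, writing and reporting of the pipeline's tabular data.

All tables are comma-separated UTF-8 with a header row and decimal points.
Readers validate schemas up front and name the offending column or row in
their errors; the survey reader checks the stop rule (no activity in a
quadrat after its first detection) and warns — or errors, if configured —
on violations so messy field data still load by default.
"""
from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, StopRuleViolationWarning
from .types import (
    ManagementUnit,
    MUEstimate,
    PlaybackTrial,
    Quadrat,
    SurveyPoint,
    size_class_for_area,
)

_TRUTHY = {"1", "yes", "y", "true", "t"}
_FALSY = {"0", "no", "n", "false", "f", ""}

TRIAL_COLUMNS = ("group_id", "distance_m", "fragment_class", "group_size", "detected")
SURVEY_COLUMNS = ("mu_name", "quadrat_id", "point_index", "detected", "n_individuals")
MU_COLUMNS = ("mu_name", "forest_area_ha", "management_type")


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


def _coerce_detected(series: pd.Series, what: str) -> pd.Series:
    def one(val, row):
        s = str(val).strip().lower()
        if s in _TRUTHY:
            return 1
        if s in _FALSY:
            return 0
        raise ParseError(f"{what} row {row}: cannot read detected value {val!r}")

    return pd.Series(
        [one(v, i + 2) for i, v in enumerate(series)], index=series.index, dtype=int
    )  # row numbers count the header as line 1


def _coerce_float(series: pd.Series, col: str, what: str) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna()
    if bad.any():
        row = int(bad.idxmax()) + 2
        raise ParseError(
            f"{what} row {row}: non-numeric {col} value {series[bad.idxmax()]!r}"
        )
    return out


def read_trials(path) -> list[PlaybackTrial]:
    """Read a playback-trial table (one lure presentation per row)."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, TRIAL_COLUMNS, "trial")
    if df.empty:
        return []
    dist = _coerce_float(df["distance_m"], "distance_m", "trial")
    size = _coerce_float(df["group_size"], "group_size", "trial")
    det = _coerce_detected(df["detected"], "trial")
    return [
        PlaybackTrial(
            group_id=str(g),
            distance_m=float(d),
            fragment_class=str(fc).strip().lower(),
            group_size=int(s),
            detected=int(y),
        )
        for g, d, fc, s, y in zip(
            df["group_id"], dist, df["fragment_class"], size, det
        )
    ]


def write_trials(trials: Sequence[PlaybackTrial], path) -> None:
    pd.DataFrame(
        {
            "group_id": [t.group_id for t in trials],
            "distance_m": [t.distance_m for t in trials],
            "fragment_class": [t.fragment_class for t in trials],
            "group_size": [t.group_size for t in trials],
            "detected": [t.detected for t in trials],
        }
    ).to_csv(path, index=False)


def read_survey(path, stop_rule_violation: str = "warn") -> list[Quadrat]:
    """Read a survey-point table and group the points by quadrat.

    Points are ordered by point_index within each quadrat. A row recording
    activity after a quadrat's first detection violates the stop rule; it is
    kept but reported (warning by default, error if requested).
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, SURVEY_COLUMNS, "survey")
    quadrats: list[Quadrat] = []
    if df.empty:
        return quadrats
    df = df.assign(
        point_index=_coerce_float(df["point_index"], "point_index", "survey").astype(int),
        detected=_coerce_detected(df["detected"], "survey"),
        n_individuals=pd.to_numeric(df["n_individuals"], errors="coerce"),
    )
    for (mu, qid), block in df.groupby(["mu_name", "quadrat_id"], sort=False):
        block = block.sort_values("point_index")
        det = block["detected"].to_numpy()
        if det.any() and det.argmax() < len(det) - 1:
            msg = (
                f"quadrat {qid!r} records points after its first detection "
                f"(stop-rule violation)"
            )
            if stop_rule_violation == "error":
                raise SchemaError(msg)
            warnings.warn(msg, StopRuleViolationWarning, stacklevel=2)
        points = tuple(
            SurveyPoint(
                mu_name=str(mu),
                quadrat_id=str(qid),
                point_index=int(r.point_index),
                detected=int(r.detected),
                n_individuals=(
                    int(r.n_individuals) if np.isfinite(r.n_individuals) else None
                ),
            )
            for r in block.itertuples()
        )
        quadrats.append(Quadrat(mu_name=str(mu), quadrat_id=str(qid), points=points))
    return quadrats


def write_survey(quadrats: Sequence[Quadrat], path) -> None:
    rows = [
        {
            "mu_name": p.mu_name,
            "quadrat_id": p.quadrat_id,
            "point_index": p.point_index,
            "detected": p.detected,
            "n_individuals": "" if p.n_individuals is None else p.n_individuals,
        }
        for q in quadrats
        for p in q.points
    ]
    pd.DataFrame(rows, columns=list(SURVEY_COLUMNS)).to_csv(path, index=False)


def read_management_units(path, size_class_threshold_km2: float = 10.0) -> list[ManagementUnit]:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, MU_COLUMNS, "management-unit")
    area = _coerce_float(df["forest_area_ha"], "forest_area_ha", "management-unit")
    units = []
    for i, (_, r) in enumerate(df.iterrows()):
        a = float(area.iloc[i])
        if "size_class" in df.columns and pd.notna(r["size_class"]):
            sc = str(r["size_class"]).strip().lower()
        else:
            sc = size_class_for_area(a / 100.0, size_class_threshold_km2)
        units.append(
            ManagementUnit(
                name=str(r["mu_name"]),
                forest_area_ha=a,
                size_class=sc,
                management_type=str(r["management_type"]).strip().lower(),
            )
        )
    return units


def estimates_to_frame(estimates: Sequence[MUEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mu_name": [e.unit.name for e in estimates],
            "group_density_per_km2": [e.group_density_per_km2 for e in estimates],
            "individual_density_per_km2": [e.individual_density_per_km2 for e in estimates],
            "group_size": [e.group_size for e in estimates],
            "forest_area_ha": [e.unit.forest_area_ha for e in estimates],
            "population_size": [e.population_size for e in estimates],
            "ci_low": [e.ci_low for e in estimates],
            "ci_high": [e.ci_high for e in estimates],
            "management_type": [e.unit.management_type for e in estimates],
        }
    )


def read_estimates(path, size_class_threshold_km2: float = 10.0) -> list[MUEstimate]:
    """Read a per-MU estimate table (the report_mu_table schema, minus totals)."""
    df = pd.read_csv(path)
    _require_columns(
        df,
        ("mu_name", "group_density_per_km2", "individual_density_per_km2",
         "group_size", "forest_area_ha", "population_size", "ci_low", "ci_high",
         "management_type"),
        "estimate",
    )
    out = []
    for _, r in df.iterrows():
        area_ha = float(r["forest_area_ha"])
        unit = ManagementUnit(
            name=str(r["mu_name"]),
            forest_area_ha=area_ha,
            size_class=size_class_for_area(area_ha / 100.0, size_class_threshold_km2),
            management_type=str(r["management_type"]).strip().lower(),
        )
        out.append(
            MUEstimate(
                unit=unit,
                group_density_per_km2=float(r["group_density_per_km2"]),
                individual_density_per_km2=float(r["individual_density_per_km2"]),
                group_size=float(r["group_size"]),
                population_size=int(r["population_size"]),
                ci_low=float(r["ci_low"]),
                ci_high=float(r["ci_high"]),
            )
        )
    return out


def load_reference_estimates() -> list[MUEstimate]:
    """The packaged 2014 range-wide survey results for the seven MUs.

    Shipped as reference data so that report aggregation and viability runs
    can be exercised (and the published totals reproduced) without any
    download.
    """
    with resources.files("lurepoint.data").joinpath(
        "survey_2014_management_units.csv"
    ).open("r") as fh:
        return read_estimates(fh)


def report_mu_table(
    estimates: Sequence[MUEstimate],
    density_decimals: int = 1,
    group_density_decimals: int = 2,
) -> pd.DataFrame:
    """Render the per-MU results table with an exact totals row.

    Totals of forest area and population are exact sums; the totals-row
    densities are recomputed as area-weighted means (individual density =
    total population / total forest area), not transcribed. Densities are
    rounded for display; populations are whole individuals.
    """
    if not estimates:
        raise SchemaError("report needs >= 1 estimate")
    names = [e.unit.name for e in estimates]
    if len(set(names)) != len(names):
        raise SchemaError("duplicate MU names in estimates")
    df = estimates_to_frame(estimates)
    total_area_ha = df["forest_area_ha"].sum()
    total_pop = int(df["population_size"].sum())
    area_km2 = df["forest_area_ha"] / 100.0
    totals = pd.DataFrame(
        {
            "mu_name": ["Total"],
            "group_density_per_km2": [
                (df["group_density_per_km2"] * area_km2).sum() / (total_area_ha / 100.0)
            ],
            "individual_density_per_km2": [total_pop / (total_area_ha / 100.0)],
            "group_size": [df["group_size"].mean()],
            "forest_area_ha": [total_area_ha],
            "population_size": [total_pop],
            "ci_low": [df["ci_low"].sum()],
            "ci_high": [df["ci_high"].sum()],
            "management_type": [""],
        }
    )
    out = pd.concat([df, totals], ignore_index=True)
    out["group_density_per_km2"] = out["group_density_per_km2"].round(group_density_decimals)
    out["individual_density_per_km2"] = out["individual_density_per_km2"].round(density_decimals)
    out["group_size"] = out["group_size"].round(2)
    return out
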