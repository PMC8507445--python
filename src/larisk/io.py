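"""File formats, run configuration and analysis drivers.

Interchange formats (comma-separated, UTF-8, dot decimal, mandatory header):

* life tables: ``sex,age,lx`` — ``lx`` is survivorship or raw counts
  (auto-normalized so l(0) = 1); one file may hold both sexes;
* baseline rates: ``site,sex,age,rate_per_100k,kind``;
* dose coefficients: ``radiopharmaceutical,organ,age_group,mGy_per_MBq``
  with ``age_group`` in {1, 5, 10, 15, adult};
* risk models: TOML with one ``[[model]]`` block per (site, sex);
* run configuration: TOML, see :class:`RunConfig`.

The drivers :func:`run_lar_curve` and :func:`run_protocol` chain the stages
into the package's standard analyses and write deterministic CSV/JSON
outputs embedding a digest of the inputs used.
"""
from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from .dosimetry import AGE_GROUPS, DoseCoefficientTable, organ_doses
from .errors import DataValidationError, TableFormatError
from .lar_engine import LARResult, lar_total
from .lifetables import (COHORT_PRESETS, CohortSurvivalSpec, LifeTable,
                         lifetable_from_survivorship)
from .protocol import ProtocolPoint, protocol_table
from .risk_models import BaselineRateTable, ExposureScenario, RiskModelParams

__all__ = [
    "RunConfig", "TableBundle",
    "read_life_tables", "write_life_tables",
    "read_baseline_rates", "write_baseline_rates",
    "read_dose_coefficients", "write_dose_coefficients",
    "read_risk_models", "write_risk_models",
    "read_tables", "make_lar_fn", "run_lar_curve", "run_protocol",
    "one_in",
]

_FLOAT_FMT = "%.10g"


def _read_csv(path, required: set[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TableFormatError("file not found", path=str(path))
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise TableFormatError(f"could not parse CSV: {exc}", path=str(path)) from exc
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"missing required column(s) {sorted(missing)}",
                               path=str(path))
    return df


def _numeric(df: pd.DataFrame, column: str, path) -> np.ndarray:
    values = pd.to_numeric(df[column], errors="coerce")
    bad = values.isna() & df[column].notna() | df[column].isna()
    if bad.any():
        row = int(np.argmax(bad.to_numpy()))
        raise TableFormatError(
            f"non-numeric value {df[column].iloc[row]!r}",
            path=str(path), line=row + 2, column=column)
    return values.to_numpy(dtype=float)


# ---------------------------------------------------------------- life tables

def read_life_tables(path) -> dict[str, LifeTable]:
    df = _read_csv(path, {"sex", "age", "lx"})
    _numeric(df, "age", path)
    _numeric(df, "lx", path)
    out = {}
    for sex, grp in df.groupby("sex", sort=True):
        grp = grp.sort_values("age")
        try:
            out[str(sex)] = lifetable_from_survivorship(
                str(sex), grp["age"].to_numpy(dtype=int), grp["lx"].to_numpy(dtype=float))
        except DataValidationError as exc:
            raise TableFormatError(str(exc), path=str(path), column="lx") from exc
    if not out:
        raise TableFormatError("no rows", path=str(path))
    return out


def write_life_tables(tables: dict[str, LifeTable], path) -> None:
    frames = [pd.DataFrame({"sex": t.sex, "age": t.ages, "lx": t.survivorship})
              for _, t in sorted(tables.items())]
    pd.concat(frames).to_csv(path, index=False, float_format=_FLOAT_FMT)


# ------------------------------------------------------------- baseline rates

def read_baseline_rates(path) -> dict[tuple[str, str, str], BaselineRateTable]:
    df = _read_csv(path, {"site", "sex", "age", "rate_per_100k", "kind"})
    _numeric(df, "age", path)
    _numeric(df, "rate_per_100k", path)
    out = {}
    for (site, sex, kind), grp in df.groupby(["site", "sex", "kind"], sort=True):
        grp = grp.sort_values("age")
        try:
            out[(site, sex, kind)] = BaselineRateTable(
                site=site, sex=sex, kind=kind,
                ages=grp["age"].to_numpy(dtype=float),
                rates=grp["rate_per_100k"].to_numpy(dtype=float))
        except DataValidationError as exc:
            raise TableFormatError(str(exc), path=str(path)) from exc
    return out


def write_baseline_rates(tables: dict, path) -> None:
    frames = [pd.DataFrame({"site": t.site, "sex": t.sex, "age": t.ages,
                            "rate_per_100k": t.rates, "kind": t.kind})
              for _, t in sorted(tables.items())]
    pd.concat(frames).to_csv(path, index=False, float_format=_FLOAT_FMT)


# --------------------------------------------------------- dose coefficients

def read_dose_coefficients(path, bone_seeker: bool = True) -> DoseCoefficientTable:
    df = _read_csv(path, {"radiopharmaceutical", "organ", "age_group", "mGy_per_MBq"})
    _numeric(df, "mGy_per_MBq", path)
    pharms = df["radiopharmaceutical"].unique()
    if len(pharms) != 1:
        raise TableFormatError(
            f"expected one radiopharmaceutical per file, found {list(pharms)}",
            path=str(path), column="radiopharmaceutical")
    groups = [str(g) for g in df["age_group"]]
    unknown = sorted(set(groups) - set(AGE_GROUPS))
    if unknown:
        raise TableFormatError(f"unknown age_group(s) {unknown}; expected {AGE_GROUPS}",
                               path=str(path), column="age_group")
    coeffs = {}
    for organ, grp in df.groupby("organ", sort=True):
        by_group = dict(zip((str(g) for g in grp["age_group"]),
                            grp["mGy_per_MBq"].astype(float)))
        missing = [g for g in AGE_GROUPS if g not in by_group]
        if missing:
            raise TableFormatError(
                f"organ {organ!r} missing age group(s) {missing}",
                path=str(path), column="age_group")
        coeffs[str(organ)] = np.array([by_group[g] for g in AGE_GROUPS])
    try:
        return DoseCoefficientTable(radiopharmaceutical=str(pharms[0]),
                                    coefficients=coeffs, bone_seeker=bone_seeker)
    except DataValidationError as exc:
        raise TableFormatError(str(exc), path=str(path)) from exc


def write_dose_coefficients(table: DoseCoefficientTable, path) -> None:
    rows = [{"radiopharmaceutical": table.radiopharmaceutical, "organ": organ,
             "age_group": g, "mGy_per_MBq": v}
            for organ in sorted(table.organs)
            for g, v in zip(AGE_GROUPS, table.coefficients[organ])]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------- risk models

def read_risk_models(path) -> dict[tuple[str, str], RiskModelParams]:
    path = Path(path)
    if not path.exists():
        raise TableFormatError("file not found", path=str(path))
    try:
        data = tomllib.loads(path.read_text())
    except tomllib.TOMLDecodeError as exc:
        raise TableFormatError(f"could not parse TOML: {exc}", path=str(path)) from exc
    out = {}
    for i, block in enumerate(data.get("model", [])):
        try:
            p = RiskModelParams(**block)
        except ValidationError as exc:
            raise TableFormatError(f"invalid model block #{i + 1}: {exc}",
                                   path=str(path)) from exc
        out[(p.site, p.sex)] = p
    if not out:
        raise TableFormatError("no [[model]] blocks", path=str(path))
    return out


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return '"' + str(v).replace('"', '\\"') + '"'


def write_risk_models(params: dict[tuple[str, str], RiskModelParams], path) -> None:
    lines = []
    for key in sorted(params):
        lines.append("[[model]]")
        for name, value in params[key].model_dump().items():
            lines.append(f"{name} = {_toml_value(value)}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ------------------------------------------------------------- run config

class ScenarioConfig(BaseModel):
    sexes: list[Literal["male", "female"]] = ["male", "female"]
    ages: list[float] | None = None
    age_range: tuple[int, int] = (0, 90)  # inclusive, 1-year steps
    activity_MBq: float = Field(default=500.0, gt=0.0)
    kind: Literal["incidence", "mortality"] = "incidence"
    cohort: str | None = None

    def age_grid(self) -> list[float]:
        if self.ages is not None:
            return list(self.ages)
        lo, hi = self.age_range
        return [float(a) for a in range(lo, hi + 1)]


class ProtocolSettings(BaseModel):
    reference_activity_MBq: float = Field(default=500.0, gt=0.0)
    reference_time_min: float = Field(default=4.0, gt=0.0)
    time_window_min: tuple[float, float] = (3.0, 5.0)
    target_scope: Literal["per_sex", "combined"] = "per_sex"


class CohortConfig(BaseModel):
    k_year_survival: float = Field(gt=0.0, le=1.0)
    k_years: int = Field(ge=1)
    window_years: int | None = Field(default=None, ge=1)


class RunConfig(BaseModel):
    """One analysis run: input paths, scenario grid and protocol settings."""

    life_tables: Path
    baseline_rates: Path
    dose_coefficients: Path
    risk_models: Path
    bone_seeker: bool = True
    scenario: ScenarioConfig = ScenarioConfig()
    protocol: ProtocolSettings = ProtocolSettings()
    cohorts: dict[str, CohortConfig] = {}
    output_dir: Path = Path(".")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        path = Path(path)
        try:
            data = tomllib.loads(path.read_text())
        except (OSError, tomllib.TOMLDecodeError) as exc:
            raise TableFormatError(f"could not read run config: {exc}",
                                   path=str(path)) from exc
        inputs = data.pop("inputs", {})
        try:
            cfg = cls(**inputs, **data)
        except ValidationError as exc:
            raise TableFormatError(f"invalid run config: {exc}", path=str(path)) from exc
        base = path.parent
        resolve = lambda p: p if p.is_absolute() else base / p
        return cfg.model_copy(update={
            "life_tables": resolve(cfg.life_tables),
            "baseline_rates": resolve(cfg.baseline_rates),
            "dose_coefficients": resolve(cfg.dose_coefficients),
            "risk_models": resolve(cfg.risk_models),
            "output_dir": resolve(cfg.output_dir),
        })

    def cohort_specs(self) -> dict[str, CohortSurvivalSpec]:
        specs = dict(COHORT_PRESETS)
        for name, c in self.cohorts.items():
            specs[name] = CohortSurvivalSpec(
                name=name, k_year_fraction=c.k_year_survival, k=c.k_years,
                window=c.window_years)
        return specs


@dataclass(frozen=True)
class TableBundle:
    """All validated inputs for one run."""

    lifetables: dict[str, LifeTable]
    baselines: dict[tuple[str, str, str], BaselineRateTable]
    dose_table: DoseCoefficientTable
    risk_params: dict[tuple[str, str], RiskModelParams]
    cohorts: dict[str, CohortSurvivalSpec] = field(default_factory=dict)
    inputs_digest: str = ""


def inputs_digest(*paths) -> str:
    h = hashlib.sha256()
    for p in paths:
        h.update(Path(p).read_bytes())
    return h.hexdigest()[:16]


def read_tables(config: RunConfig) -> TableBundle:
    """Load and validate every input referenced by the run config."""
    return TableBundle(
        lifetables=read_life_tables(config.life_tables),
        baselines=read_baseline_rates(config.baseline_rates),
        dose_table=read_dose_coefficients(config.dose_coefficients, config.bone_seeker),
        risk_params=read_risk_models(config.risk_models),
        cohorts=config.cohort_specs(),
        inputs_digest=inputs_digest(config.life_tables, config.baseline_rates,
                                    config.dose_coefficients, config.risk_models),
    )


# ---------------------------------------------------------------- drivers

def make_lar_fn(bundle, *, kind: str = "incidence", cohort: str | None = None):
    """Close over a table bundle as a ``lar_fn(sex, age, activity) -> total LAR``."""

    def lar_fn(sex: str, age: float, activity: float) -> float:
        return compute_lar(bundle, sex, age, activity, kind=kind, cohort=cohort).total

    return lar_fn


def compute_lar(bundle, sex: str, age: float, activity: float, *,
                kind: str = "incidence", cohort: str | None = None) -> LARResult:
    """Organ doses then per-site LAR for one (sex, age, activity)."""
    scenario = ExposureScenario(sex=sex, e=age, administered_activity=activity,
                                cohort=cohort)
    doses = organ_doses(bundle.dose_table, activity, age)
    return lar_total(scenario, bundle.risk_params, bundle.baselines,
                     bundle.lifetables[sex], doses, kind=kind,
                     cohorts=getattr(bundle, "cohorts", None),
                     inputs_digest=getattr(bundle, "inputs_digest", ""))


def one_in(lar: float) -> float | None:
    """Render a risk as '1 in N' with N rounded to two significant figures."""
    if lar <= 0:
        return None
    n = 1.0 / lar
    mag = 10.0 ** np.floor(np.log10(n) - 1)
    return float(round(n / mag) * mag)


def run_lar_curve(config: RunConfig, bundle: TableBundle | None = None
                  ) -> tuple[pd.DataFrame, dict]:
    """LAR (per site + total) on the scenario (sex, age) grid; write CSV + JSON."""
    if bundle is None:
        bundle = read_tables(config)
    sc = config.scenario
    rows, report_rows = [], []
    for sex in sc.sexes:
        for age in sc.age_grid():
            res = compute_lar(bundle, sex, age, sc.activity_MBq,
                              kind=sc.kind, cohort=sc.cohort)
            for site, v in res.per_site.items():
                rows.append({"site": site, "sex": sex, "age_at_exposure": age,
                             "kind": sc.kind, "lar": v})
            rows.append({"site": "total", "sex": sex, "age_at_exposure": age,
                         "kind": sc.kind, "lar": res.total})
            report_rows.append({"sex": sex, "age_at_exposure": age,
                                "total_lar": res.total, "one_in": one_in(res.total)})
    df = pd.DataFrame(rows)
    report = {"kind": sc.kind, "cohort": sc.cohort,
              "activity_MBq": sc.activity_MBq,
              "inputs_digest": bundle.inputs_digest, "rows": report_rows}
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    suffix = f"_{sc.cohort}" if sc.cohort else ""
    df.to_csv(out / f"lar_curve{suffix}.csv", index=False, float_format=_FLOAT_FMT)
    (out / f"lar_report{suffix}.json").write_text(
        json.dumps(report, indent=2, sort_keys=True))
    return df, report


def run_protocol(config: RunConfig, bundle: TableBundle | None = None) -> pd.DataFrame:
    """Equal-risk protocol table on the scenario grid; write CSV."""
    if bundle is None:
        bundle = read_tables(config)
    sc, pr = config.scenario, config.protocol
    lar_fn = make_lar_fn(bundle, kind=sc.kind, cohort=sc.cohort)
    points = protocol_table(lar_fn, sc.sexes, sc.age_grid(),
                            A_ref=pr.reference_activity_MBq,
                            t_ref=pr.reference_time_min,
                            window=pr.time_window_min,
                            target_scope=pr.target_scope)
    df = protocol_points_frame(points)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "protocol.csv", index=False, float_format=_FLOAT_FMT)
    return df


def protocol_points_frame(points: list[ProtocolPoint]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sex": p.sex, "age": p.age, "activity_MBq": p.activity,
        "acq_time_min": p.acquisition_time, "achieved_lar": p.achieved_lar,
        "clamped": p.clamped, "unclamped_time_min": p.unclamped_time,
    } for p in points])
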