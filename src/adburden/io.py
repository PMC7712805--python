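"""CSV/YAML readers and writers, scenario configuration, run manifest, report.

All schemas use decimal points and UTF-8 regardless of source locale;
currency is EUR end-to-end.  Every reader validates the type invariants on
load and raises :class:`SchemaError` naming the file and the violated rule.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from importlib import metadata, resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .costs import (
    AGE_BANDS,
    CATEGORIES,
    CostProjection,
    MedicalUnitCostTable,
    NonResidentialService,
    ResidentialService,
    TreatedShareTable,
    per_person_costs,
)
from .population import (
    AGE_MIN,
    AGE_MAX,
    N_AGES,
    N_COHORTS,
    STAGES,
    STATES,
    ADState,
    PopulationProjection,
    PrevalenceCurve,
    TransitionMatrix,
)

__all__ = [
    "SchemaError",
    "ScenarioConfig",
    "read_scenario",
    "read_projection",
    "write_projection",
    "read_prevalence",
    "write_prevalence",
    "read_transition_matrix",
    "write_transition_matrix",
    "read_medical_costs",
    "write_medical_costs",
    "read_treated_shares",
    "write_treated_shares",
    "read_residential",
    "write_residential",
    "read_nonresidential",
    "write_nonresidential",
    "trajectory_frame",
    "summary_frame",
    "write_trajectory",
    "read_trajectory",
    "fixture_medical_costs",
    "fixture_residential",
    "fixture_nonresidential",
    "reference_cost_summary",
    "reference_per_person",
    "load_population_inputs",
    "write_bundle",
    "write_manifest",
    "report",
]


class SchemaError(ValueError):
    """An input file violated its schema or a type invariant."""


def _fail(path, message: str) -> "SchemaError":
    return SchemaError(f"{path}: {message}")


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise _fail(path, f"missing columns {sorted(missing)}")


def _age_to_bin(value, path) -> int:
    s = str(value).strip()
    if s == "95+":
        return AGE_MAX
    try:
        age = int(s)
    except ValueError:
        raise _fail(path, f"unparseable age {value!r}") from None
    if not 0 <= age <= 94:
        raise _fail(path, f"age {age} outside 0-94 (use '95+' for the top bin)")
    return age


def _bin_to_age(age: int) -> str:
    return "95+" if age >= AGE_MAX else str(age)


# ---------------------------------------------------------------------------
# scenario configuration
# ---------------------------------------------------------------------------


class ScenarioConfig(BaseModel):
    """One simulation scenario; file paths are relative to the YAML file."""

    region: str
    start_year: int
    end_year: int
    projection: Path
    prevalence: Path
    transition_matrix: Path
    medical_costs: Path | None = None
    treated_shares: Path | None = None
    residential_services: Path | None = None
    nonresidential_services: Path | None = None
    calibration_tolerance: float = Field(default=1e-6, gt=0)
    limit_tolerance: float = Field(default=1e-8, gt=0)
    max_iterations: int = Field(default=200, ge=1)
    seed: int = 0  # used only by synthetic generation

    @model_validator(mode="after")
    def _check_years(self) -> "ScenarioConfig":
        if self.start_year >= self.end_year:
            raise ValueError("start_year must precede end_year")
        return self

    def resolve(self, base: Path) -> "ScenarioConfig":
        updates = {}
        for name in ("projection", "prevalence", "transition_matrix",
                     "medical_costs", "treated_shares",
                     "residential_services", "nonresidential_services"):
            value = getattr(self, name)
            if value is not None and not Path(value).is_absolute():
                updates[name] = (base / value).resolve()
        return self.model_copy(update=updates)


def read_scenario(path) -> ScenarioConfig:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    try:
        config = ScenarioConfig.model_validate(raw)
    except Exception as exc:
        raise _fail(path, f"invalid scenario: {exc}") from exc
    return config.resolve(path.parent)


def write_scenario(config: ScenarioConfig, path) -> Path:
    path = Path(path)
    data = json.loads(config.model_dump_json())
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return path


# ---------------------------------------------------------------------------
# population-side schemas
# ---------------------------------------------------------------------------


def read_projection(path, region: str | None = None) -> PopulationProjection:
    """Long-format CSV ``region,year,age,count`` with ages 0-94 and ``95+``."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"age": str})
    _require_columns(df, ("region", "year", "age", "count"), path)
    if region is not None:
        df = df[df["region"] == region]
        if df.empty:
            raise _fail(path, f"no rows for region {region!r}")
    elif df["region"].nunique() != 1:
        raise _fail(path, "multiple regions present; pass region= to select one")
    df = df.assign(age_bin=[_age_to_bin(a, path) for a in df["age"]])
    years = np.sort(df["year"].unique())
    wide = df.pivot_table(index="age_bin", columns="year", values="count",
                          aggfunc="sum")
    missing_ages = sorted(set(range(N_COHORTS)) - set(wide.index))
    if missing_ages:
        label = _bin_to_age(missing_ages[0])
        raise _fail(path, f"projection incomplete: missing age cohort '{label}'")
    counts = wide.loc[np.arange(N_COHORTS), years].to_numpy(dtype=float)
    if np.isnan(counts).any():
        raise _fail(path, "projection has missing (age, year) cells")
    try:
        return PopulationProjection(region=str(df["region"].iloc[0]),
                                    years=years, counts=counts)
    except ValueError as exc:
        raise _fail(path, str(exc)) from exc


def write_projection(projection: PopulationProjection, path) -> Path:
    path = Path(path)
    records = []
    for j, year in enumerate(projection.years):
        for a in range(N_COHORTS):
            records.append(
                (projection.region, int(year), _bin_to_age(a),
                 projection.counts[a, j])
            )
    pd.DataFrame(records, columns=["region", "year", "age", "count"]).to_csv(
        path, index=False
    )
    return path


def read_prevalence(path) -> PrevalenceCurve:
    """CSV ``age,prevalence`` for ages 65..94 plus ``95+``."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"age": str})
    _require_columns(df, ("age", "prevalence"), path)
    values = np.full(N_AGES, np.nan)
    for _, row in df.iterrows():
        age = _age_to_bin_senior(row["age"], path)
        values[age - AGE_MIN] = float(row["prevalence"])
    if np.isnan(values).any():
        missing = AGE_MIN + int(np.argmax(np.isnan(values)))
        raise _fail(path, f"prevalence missing age {_bin_to_age(missing)}")
    try:
        return PrevalenceCurve(values=values)
    except ValueError as exc:
        raise _fail(path, str(exc)) from exc


def _age_to_bin_senior(value, path) -> int:
    s = str(value).strip()
    if s == "95+":
        return AGE_MAX
    try:
        age = int(s)
    except ValueError:
        raise _fail(path, f"unparseable age {value!r}") from None
    if not AGE_MIN <= age <= 94:
        raise _fail(path, f"age {age} outside 65-94 (use '95+' for the top bin)")
    return age


def write_prevalence(curve: PrevalenceCurve, path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "age": [_bin_to_age(AGE_MIN + i) for i in range(N_AGES)],
        "prevalence": curve.values,
    }).to_csv(path, index=False)
    return path


def read_transition_matrix(path) -> TransitionMatrix:
    """4x4 CSV with header row/column ``mild,moderate,severe,death``."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(STATES) or list(df.columns) != list(STATES):
        raise _fail(path, f"expected row/column labels {list(STATES)}")
    values = df.to_numpy(dtype=float)
    row_sums = values.sum(axis=1)
    bad = np.nonzero(np.abs(row_sums - 1.0) > 1e-12)[0]
    if bad.size:
        raise _fail(
            path,
            f"row '{STATES[bad[0]]}' sums to {row_sums[bad[0]]:.6f}, not 1",
        )
    try:
        return TransitionMatrix(probabilities=values)
    except ValueError as exc:
        raise _fail(path, str(exc)) from exc


def write_transition_matrix(matrix: TransitionMatrix, path) -> Path:
    path = Path(path)
    pd.DataFrame(matrix.probabilities, index=list(STATES),
                 columns=list(STATES)).to_csv(path)
    return path


# ---------------------------------------------------------------------------
# cost-side schemas
# ---------------------------------------------------------------------------


def read_medical_costs(path, region: str) -> MedicalUnitCostTable:
    """CSV ``region,stage,age_band,category,eur_per_treated_year``."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(
        df, ("region", "stage", "age_band", "category", "eur_per_treated_year"), path
    )
    df = df[df["region"] == region]
    if df.empty:
        raise _fail(path, f"no medical costs for region {region!r}")
    table = df.pivot_table(index=["stage", "age_band"], columns="category",
                           values="eur_per_treated_year", aggfunc="first")
    try:
        return MedicalUnitCostTable(region=region, table=table)
    except ValueError as exc:
        raise _fail(path, str(exc)) from exc


def write_medical_costs(costs: MedicalUnitCostTable, path) -> Path:
    path = Path(path)
    records = [
        (costs.region, stage, band, category,
         costs.table.loc[(stage, band), category])
        for stage in STAGES for band in AGE_BANDS for category in CATEGORIES
    ]
    pd.DataFrame(records, columns=[
        "region", "stage", "age_band", "category", "eur_per_treated_year",
    ]).to_csv(path, index=False)
    return path


def read_treated_shares(path, region: str) -> TreatedShareTable:
    """CSV ``region,stage,share``."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("region", "stage", "share"), path)
    df = df[df["region"] == region]
    if df.empty:
        raise _fail(path, f"no treated shares for region {region!r}")
    try:
        return TreatedShareTable(
            region=region, shares=dict(zip(df["stage"], df["share"].astype(float)))
        )
    except ValueError as exc:
        raise _fail(path, str(exc)) from exc


def write_treated_shares(shares: TreatedShareTable, path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "region": shares.region,
        "stage": list(STAGES),
        "share": [shares.shares[s] for s in STAGES],
    }).to_csv(path, index=False)
    return path


def read_residential(path, region: str) -> list[ResidentialService]:
    """CSV ``region,service,beds,ad_share,eur_per_bed_day``."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("region", "service", "beds", "ad_share",
                          "eur_per_bed_day"), path)
    df = df[df["region"] == region]
    try:
        return [
            ResidentialService(name=row["service"], capacity=int(row["beds"]),
                               ad_share=float(row["ad_share"]),
                               unit_cost=float(row["eur_per_bed_day"]))
            for _, row in df.iterrows()
        ]
    except ValueError as exc:
        raise _fail(path, str(exc)) from exc


def write_residential(services: list[ResidentialService], region: str, path) -> Path:
    path = Path(path)
    pd.DataFrame([
        (region, s.name, s.capacity, s.ad_share, s.unit_cost) for s in services
    ], columns=["region", "service", "beds", "ad_share", "eur_per_bed_day"]
    ).to_csv(path, index=False)
    return path


def read_nonresidential(path, region: str) -> list[NonResidentialService]:
    """CSV ``region,service,fte,ad_share,eur_per_fte_month``."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("region", "service", "fte", "ad_share",
                          "eur_per_fte_month"), path)
    df = df[df["region"] == region]
    try:
        return [
            NonResidentialService(name=row["service"], capacity=float(row["fte"]),
                                  ad_share=float(row["ad_share"]),
                                  unit_cost=float(row["eur_per_fte_month"]))
            for _, row in df.iterrows()
        ]
    except ValueError as exc:
        raise _fail(path, str(exc)) from exc


def write_nonresidential(services: list[NonResidentialService], region: str,
                         path) -> Path:
    path = Path(path)
    pd.DataFrame([
        (region, s.name, s.capacity, s.ad_share, s.unit_cost) for s in services
    ], columns=["region", "service", "fte", "ad_share", "eur_per_fte_month"]
    ).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# trajectory output schema
# ---------------------------------------------------------------------------


def trajectory_frame(trajectory: list[ADState], region: str) -> pd.DataFrame:
    """Long format ``region,year,age,stage,count``."""
    records = []
    for state in trajectory:
        for i in range(N_AGES):
            for j, stage in enumerate(STAGES):
                records.append((region, state.year, _bin_to_age(AGE_MIN + i),
                                stage, state.ad_counts[i, j]))
    return pd.DataFrame(records, columns=["region", "year", "age", "stage", "count"])


def summary_frame(trajectory: list[ADState], region: str) -> pd.DataFrame:
    """Per-year summary ``region,year,ad_total,mild,moderate,severe``."""
    rows = []
    for state in trajectory:
        mild, moderate, severe = state.stage_totals()
        rows.append((region, state.year, state.ad_total, mild, moderate, severe))
    return pd.DataFrame(rows, columns=["region", "year", "ad_total",
                                       "mild", "moderate", "severe"])


def write_trajectory(trajectory: list[ADState], region: str, path) -> Path:
    path = Path(path)
    trajectory_frame(trajectory, region).to_csv(path, index=False)
    return path


def read_trajectory(path, region: str | None = None) -> list[ADState]:
    """Rebuild ADStates from a trajectory CSV.

    The CSV carries AD counts only; disease-free counts are not part of the
    schema and are restored as zeros (the cost model never uses them).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"age": str})
    _require_columns(df, ("region", "year", "age", "stage", "count"), path)
    if region is not None:
        df = df[df["region"] == region]
        if df.empty:
            raise _fail(path, f"no rows for region {region!r}")
    states = []
    for year in sorted(df["year"].unique()):
        sub = df[df["year"] == year]
        ad = np.zeros((N_AGES, len(STAGES)))
        for _, row in sub.iterrows():
            age = _age_to_bin_senior(row["age"], path)
            if row["stage"] not in STAGES:
                raise _fail(path, f"unknown stage {row['stage']!r}")
            ad[age - AGE_MIN, STAGES.index(row["stage"])] = float(row["count"])
        states.append(ADState(year=int(year), ad_counts=ad,
                              healthy_counts=np.zeros(N_AGES)))
    return states


# ---------------------------------------------------------------------------
# packaged fixtures (published Czech regional tables)
# ---------------------------------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(resources.files("adburden.data") / name)


def fixture_medical_costs(region: str) -> MedicalUnitCostTable:
    """Published per-treated-patient medical unit costs for ``khk``/``vys``."""
    return read_medical_costs(_data_path("medical_unit_costs.csv"), region)


def fixture_residential(region: str) -> list[ResidentialService]:
    return read_residential(_data_path("residential_services.csv"), region)


def fixture_nonresidential(region: str) -> list[NonResidentialService]:
    return read_nonresidential(_data_path("nonresidential_services.csv"), region)


def reference_cost_summary() -> pd.DataFrame:
    """Published yearly cost summary (million EUR) for the two study regions."""
    return pd.read_csv(_data_path("cost_summary_reference.csv"))


def reference_per_person() -> pd.DataFrame:
    """Published per-person annual cost components (EUR) by stage."""
    return pd.read_csv(_data_path("per_person_reference.csv"))


# ---------------------------------------------------------------------------
# orchestration helpers
# ---------------------------------------------------------------------------


def load_population_inputs(config: ScenarioConfig):
    """Load and validate the population-side inputs of a scenario.

    The projection is restricted to the configured year window.
    """
    projection = read_projection(config.projection, region=config.region)
    prevalence = read_prevalence(config.prevalence)
    transitions = read_transition_matrix(config.transition_matrix)
    i0 = projection.year_index(config.start_year)
    i1 = projection.year_index(config.end_year)
    window = PopulationProjection(
        region=projection.region,
        years=projection.years[i0:i1 + 1],
        counts=projection.counts[:, i0:i1 + 1],
    )
    return window, prevalence, transitions


def load_cost_inputs(config: ScenarioConfig):
    for name in ("medical_costs", "treated_shares", "residential_services",
                 "nonresidential_services"):
        if getattr(config, name) is None:
            raise SchemaError(f"scenario is missing the '{name}' input needed "
                              "for the cost model")
    return (
        read_medical_costs(config.medical_costs, config.region),
        read_treated_shares(config.treated_shares, config.region),
        read_residential(config.residential_services, config.region),
        read_nonresidential(config.nonresidential_services, config.region),
    )


def write_bundle(spec, out_dir, fixture: str | None = None) -> Path:
    """Write a full synthetic input bundle and its scenario YAML."""
    from . import synthetic

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    projection = synthetic.generate_projection(spec)
    prevalence = synthetic.generate_prevalence(spec)
    transitions = synthetic.generate_transition_matrix(spec)
    medical, shares, residential, nonresidential = synthetic.generate_cost_inputs(
        spec, fixture=fixture
    )
    region = medical.region

    write_projection(projection, out_dir / "projection.csv")
    write_prevalence(prevalence, out_dir / "prevalence.csv")
    write_transition_matrix(transitions, out_dir / "transition_matrix.csv")
    write_medical_costs(medical, out_dir / "medical_unit_costs.csv")
    write_treated_shares(shares, out_dir / "treated_shares.csv")
    write_residential(residential, region, out_dir / "residential_services.csv")
    write_nonresidential(nonresidential, region,
                         out_dir / "nonresidential_services.csv")

    if fixture is not None and region != projection.region:
        # fixture cost tables carry their own region id; rewrite the
        # projection under the same id so one scenario covers both
        projection = PopulationProjection(region=region, years=projection.years,
                                          counts=projection.counts)
        write_projection(projection, out_dir / "projection.csv")

    config = ScenarioConfig(
        region=region,
        start_year=int(projection.years[0]),
        end_year=int(projection.years[-1]),
        projection=Path("projection.csv"),
        prevalence=Path("prevalence.csv"),
        transition_matrix=Path("transition_matrix.csv"),
        medical_costs=Path("medical_unit_costs.csv"),
        treated_shares=Path("treated_shares.csv"),
        residential_services=Path("residential_services.csv"),
        nonresidential_services=Path("nonresidential_services.csv"),
        seed=spec.seed,
    )
    return write_scenario(config, out_dir / "scenario.yaml")


# ---------------------------------------------------------------------------
# manifest and report
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(out_dir, inputs=(), outputs=(), warnings=(),
                   config_path=None) -> Path:
    """Write the single ``manifest.json`` of an output directory."""
    out_dir = Path(out_dir)
    try:
        version = metadata.version("adburden")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    manifest = {
        "tool": "adburden",
        "version": version,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config_hash": _sha256(Path(config_path)) if config_path else None,
        "inputs": [{"path": str(p), "sha256": _sha256(Path(p))} for p in inputs],
        "outputs": [{"path": str(p), "sha256": _sha256(Path(p))} for p in outputs],
        "warnings": list(warnings),
    }
    path = out_dir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return path


def report(
    cost_projection: CostProjection,
    trajectory: list[ADState],
    out_dir,
    medical_by_stage: pd.DataFrame | None = None,
    per_person_year: int | None = None,
    chart: bool = False,
    warnings=(),
    config_path=None,
) -> dict[str, Path]:
    """Write the report files of a completed run.

    Emits the trajectory summary, the yearly cost table in million EUR, the
    per-person table in whole EUR (components rounded first so each row's
    total equals medical + non-medical exactly), an optional stage-split
    cost chart, and the run manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    region = cost_projection.region
    files: dict[str, Path] = {}

    summary = summary_frame(trajectory, region)
    files["summary"] = out_dir / "trajectory_summary.csv"
    summary.to_csv(files["summary"], index=False)

    by_year = cost_projection.by_year
    costs = pd.DataFrame({
        "region": region,
        "year": by_year.index,
        "medical_meur": (by_year["medical_eur"] / 1e6).round(3),
        "nonmedical_meur": (by_year["nonmedical_eur"] / 1e6).round(3),
    })
    costs["total_meur"] = (costs["medical_meur"] + costs["nonmedical_meur"]).round(3)
    files["costs_by_year"] = out_dir / "costs_by_year.csv"
    costs.to_csv(files["costs_by_year"], index=False)

    if per_person_year is None:
        per_person_year = int(by_year.index[0])
    try:
        pp = per_person_costs(cost_projection, trajectory, per_person_year,
                              medical_by_stage=medical_by_stage)
    except ZeroDivisionError:
        # a run with no AD population still reports, with zero columns
        pp = pd.DataFrame(0.0, index=pd.Index([*STAGES, "all"], name="stage"),
                          columns=["medical_eur_pp", "nonmedical_eur_pp",
                                   "total_eur_pp"])
    pp_out = pd.DataFrame({
        "region": region,
        "stage": pp.index,
        "medical_eur_pp": pp["medical_eur_pp"].round(0).astype(int),
        "nonmedical_eur_pp": pp["nonmedical_eur_pp"].round(0).astype(int),
    })
    pp_out["total_eur_pp"] = pp_out["medical_eur_pp"] + pp_out["nonmedical_eur_pp"]
    files["per_person"] = out_dir / "per_person_costs.csv"
    pp_out.to_csv(files["per_person"], index=False)

    if chart and cost_projection.by_stage is not None:  # pragma: no cover - optional
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 5))
        pivot = cost_projection.by_stage.pivot(index="year", columns="stage",
                                               values="total_eur") / 1e6
        pivot[list(STAGES)].plot.area(ax=ax)
        ax.set_xlabel("year")
        ax.set_ylabel("direct costs (million EUR)")
        ax.set_title(f"Direct AD costs by stage, region {region}")
        files["chart"] = out_dir / "costs_by_stage.png"
        fig.savefig(files["chart"], dpi=150)
        plt.close(fig)

    write_manifest(out_dir,
                   outputs=[p for k, p in files.items() if k != "chart"],
                   warnings=warnings, config_path=config_path)
    files["manifest"] = out_dir / "manifest.json"
    return files
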