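"""Direct-cost model: medical and non-medical (social) costs of the AD population.

Two cost streams are attached to a simulated AD trajectory:

* **Medical costs** — per-treated-patient unit costs by stage, age band and
  care category (outpatient point-system procedures, other outpatient
  services, medicines, inpatient point-system, acute inpatient care, other
  inpatient care), multiplied by the treated head-count.  The treated share
  per stage is held constant over the horizon.
* **Non-medical costs** — regional social-service inventories: residential
  capacity priced per bed per day and non-residential capacity priced per
  full-time-employee (FTE) per month, weighted by the share of capacity used
  by AD clients.  Capacities are assumed to grow with the AD population, so
  the base-year cost is scaled by a growth index; unit costs stay at constant
  base-year prices (no discounting).

All arithmetic is carried in full precision; rounding to the display
conventions (whole EUR per person, thousandths of millions for totals)
happens only in the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import ADState, AGE_MIN, N_AGES, STAGES

__all__ = [
    "AGE_BANDS",
    "CATEGORIES",
    "DAYS_PER_YEAR",
    "MONTHS_PER_YEAR",
    "MedicalUnitCostTable",
    "TreatedShareTable",
    "ResidentialService",
    "NonResidentialService",
    "CostProjection",
    "band_index",
    "medical_costs",
    "growth_index",
    "nonmedical_costs",
    "annual_inventory_cost",
    "aggregate",
    "per_person_costs",
    "project_costs",
]

AGE_BANDS: tuple[str, ...] = ("65-69", "70-79", "80-89", "90+")
CATEGORIES: tuple[str, ...] = (
    "outpatient_points",
    "outpatient_other",
    "medicines",
    "inpatient_points",
    "acute_care",
    "other_care",
)

DAYS_PER_YEAR = 365    # annualisation of per-bed-per-day residential costs
MONTHS_PER_YEAR = 12   # annualisation of per-FTE-per-month non-residential costs

# age-bin index (0 = age 65) -> band index
_BAND_OF_AGE = np.array(
    [0] * 5 + [1] * 10 + [2] * 10 + [3] * (N_AGES - 25), dtype=int
)


def band_index(age: int) -> int:
    """Map an age (65..95+) to its unit-cost age band."""
    if age < AGE_MIN:
        raise KeyError(f"age {age} below 65 has no cost band")
    return int(_BAND_OF_AGE[min(age - AGE_MIN, N_AGES - 1)])


@dataclass(frozen=True)
class MedicalUnitCostTable:
    """EUR per treated patient per year, by stage x age band x category.

    ``table`` is indexed by a (stage, age_band) MultiIndex covering all 12
    cells, with one column per care category.
    """

    region: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        expected = pd.MultiIndex.from_product(
            [STAGES, AGE_BANDS], names=["stage", "age_band"]
        )
        missing = expected.difference(self.table.index)
        if len(missing):
            raise ValueError(f"medical cost table missing cells: {list(missing)}")
        missing_cols = set(CATEGORIES) - set(self.table.columns)
        if missing_cols:
            raise ValueError(f"medical cost table missing categories: {missing_cols}")
        values = self.table.loc[expected, list(CATEGORIES)].to_numpy(dtype=float)
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("medical unit costs must be finite and non-negative")

    def per_treated_year(self) -> np.ndarray:
        """Total EUR per treated patient per year, shape (3 stages, 4 bands)."""
        expected = pd.MultiIndex.from_product(
            [STAGES, AGE_BANDS], names=["stage", "age_band"]
        )
        cells = self.table.loc[expected, list(CATEGORIES)].to_numpy(dtype=float)
        return cells.sum(axis=1).reshape(len(STAGES), len(AGE_BANDS))


@dataclass(frozen=True)
class TreatedShareTable:
    """Fraction of the AD population treated per year, per stage."""

    region: str
    shares: dict

    def __post_init__(self) -> None:
        missing = set(STAGES) - set(self.shares)
        if missing:
            raise ValueError(f"treated shares missing stages: {missing}")
        for stage, share in self.shares.items():
            if not 0.0 <= float(share) <= 1.0:
                raise ValueError(f"treated share for {stage} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([float(self.shares[s]) for s in STAGES])


@dataclass(frozen=True)
class ResidentialService:
    """Residential facility type priced per bed per day."""

    name: str
    capacity: int          # beds
    ad_share: float        # fraction of capacity used by AD clients
    unit_cost: float       # EUR per bed per day

    def __post_init__(self) -> None:
        if self.capacity < 0 or int(self.capacity) != self.capacity:
            raise ValueError(f"{self.name}: bed capacity must be a non-negative integer")
        if not 0.0 <= self.ad_share <= 1.0:
            raise ValueError(f"{self.name}: ad_share outside [0, 1]")
        if self.unit_cost < 0:
            raise ValueError(f"{self.name}: unit cost must be non-negative")


@dataclass(frozen=True)
class NonResidentialService:
    """Outpatient/domiciliary service priced per FTE per month."""

    name: str
    capacity: float        # full-time employees, may be fractional
    ad_share: float
    unit_cost: float       # EUR per FTE per month

    def __post_init__(self) -> None:
        if self.capacity < 0:
            raise ValueError(f"{self.name}: FTE capacity must be non-negative")
        if not 0.0 <= self.ad_share <= 1.0:
            raise ValueError(f"{self.name}: ad_share outside [0, 1]")
        if self.unit_cost < 0:
            raise ValueError(f"{self.name}: unit cost must be non-negative")


@dataclass(frozen=True)
class CostProjection:
    """Yearly direct-cost projection.

    ``by_year`` columns: ``medical_eur``, ``nonmedical_eur``, ``total_eur``
    indexed by calendar year.  ``by_stage`` (optional) adds the stage-split
    view with non-medical costs allocated proportionally to stage
    head-counts.
    """

    region: str
    by_year: pd.DataFrame
    by_stage: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        df = self.by_year
        gap = (df["medical_eur"] + df["nonmedical_eur"] - df["total_eur"]).abs()
        if (gap > 0.5).any():
            raise ValueError("total != medical + non-medical beyond 0.5 EUR")
        if (df[["medical_eur", "nonmedical_eur", "total_eur"]] < 0).any().any():
            raise ValueError("costs must be non-negative")


def _stage_band_counts(state: ADState) -> np.ndarray:
    """Aggregate a state's AD counts to (3 stages, 4 bands)."""
    out = np.zeros((len(STAGES), len(AGE_BANDS)))
    for band in range(len(AGE_BANDS)):
        mask = _BAND_OF_AGE == band
        out[:, band] = state.ad_counts[mask, :].sum(axis=0)
    return out


def medical_costs(
    trajectory: list[ADState],
    unit_costs: MedicalUnitCostTable,
    shares: TreatedShareTable,
) -> pd.DataFrame:
    """Annual medical costs in EUR, per year and stage.

    For each year: ``treated(stage, band) = AD count(stage, band) x
    share(stage)`` and ``cost = sum treated x unit cost`` over stages, bands
    and categories.  Exactly linear in counts, shares and unit costs.
    """
    unit = unit_costs.per_treated_year()       # (3, 4)
    share = shares.as_array()[:, None]         # (3, 1)
    rows = []
    for state in trajectory:
        counts = _stage_band_counts(state)     # (3, 4)
        cost_by_stage = (counts * share * unit).sum(axis=1)
        rows.append([state.year, *cost_by_stage])
    df = pd.DataFrame(rows, columns=["year", *STAGES]).set_index("year")
    df["total"] = df[list(STAGES)].sum(axis=1)
    return df


def growth_index(trajectory: list[ADState], base_year: int | None = None) -> pd.Series:
    """Relative AD population size per year: ``total AD(t) / total AD(base)``."""
    years = [s.year for s in trajectory]
    totals = np.array([s.ad_total for s in trajectory])
    if base_year is None:
        base_year = years[0]
    if base_year not in years:
        raise KeyError(f"base year {base_year} not in trajectory")
    base = totals[years.index(base_year)]
    if base <= 0.0:
        raise ZeroDivisionError(
            f"growth index undefined: zero AD population in base year {base_year}"
        )
    return pd.Series(totals / base, index=pd.Index(years, name="year"), name="index")


def annual_inventory_cost(
    residential: list[ResidentialService],
    nonresidential: list[NonResidentialService],
) -> float:
    """Base-year annual cost in EUR of the AD share of the service inventory."""
    res = sum(s.capacity * s.ad_share * s.unit_cost * DAYS_PER_YEAR
              for s in residential)
    nonres = sum(s.capacity * s.ad_share * s.unit_cost * MONTHS_PER_YEAR
                 for s in nonresidential)
    return float(res + nonres)


def nonmedical_costs(
    residential: list[ResidentialService],
    nonresidential: list[NonResidentialService],
    index: pd.Series,
) -> pd.Series:
    """Annual non-medical (social) costs in EUR per year.

    The base-year inventory cost is scaled by the AD growth index: capacities
    expand with the AD population while unit costs stay at constant prices.
    """
    if (index < 0).any():
        raise ValueError("growth index must be non-negative")
    return (annual_inventory_cost(residential, nonresidential) * index).rename(
        "nonmedical_eur"
    )


def aggregate(
    medical: pd.DataFrame | pd.Series,
    nonmedical: pd.Series,
    stage_counts: pd.DataFrame | None = None,
    region: str = "",
) -> CostProjection:
    """Combine medical and non-medical streams into a cost projection.

    ``medical`` may be the stage-split frame from :func:`medical_costs` or a
    plain per-year series of medical totals.  When the stage-split frame and
    per-year stage head-counts are both given, a stage view is emitted with
    non-medical costs allocated proportionally to head-counts (a presentation
    convention: social-care data cannot resolve disease stages).
    """
    if isinstance(medical, pd.DataFrame):
        med_total = medical["total"]
    else:
        med_total = medical
    if not med_total.index.equals(nonmedical.index):
        raise ValueError("medical and non-medical streams cover different years")

    by_year = pd.DataFrame({
        "medical_eur": med_total.astype(float),
        "nonmedical_eur": nonmedical.astype(float),
    })
    by_year["total_eur"] = by_year["medical_eur"] + by_year["nonmedical_eur"]
    by_year.index.name = "year"

    by_stage = None
    if isinstance(medical, pd.DataFrame) and stage_counts is not None:
        totals = stage_counts[list(STAGES)].sum(axis=1)
        rows = []
        for year in by_year.index:
            for stage in STAGES:
                head = stage_counts.loc[year, stage]
                frac = head / totals.loc[year] if totals.loc[year] > 0 else 0.0
                nm = nonmedical.loc[year] * frac
                med = medical.loc[year, stage]
                rows.append([year, stage, med, nm, med + nm])
        by_stage = pd.DataFrame(
            rows,
            columns=["year", "stage", "medical_eur", "nonmedical_eur", "total_eur"],
        )
    return CostProjection(region=region, by_year=by_year, by_stage=by_stage)


def per_person_costs(
    projection: CostProjection,
    trajectory: list[ADState],
    year: int,
    medical_by_stage: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Annual EUR per person with AD, by stage and stage-agnostic.

    Medical costs divide by the stage head-count; non-medical costs divide by
    the total AD head-count and are therefore identical across stages (the
    social-care inventories cannot be attributed to stages).  Rows are the
    three stages plus ``all``.
    """
    states = {s.year: s for s in trajectory}
    if year not in states:
        raise KeyError(f"year {year} not in trajectory")
    state = states[year]
    total_ad = state.ad_total
    if total_ad <= 0.0:
        raise ZeroDivisionError(f"no AD population in {year}: per-person costs undefined")

    nm_pp = projection.by_year.loc[year, "nonmedical_eur"] / total_ad
    med_total = projection.by_year.loc[year, "medical_eur"]
    stage_tot = dict(zip(STAGES, state.stage_totals()))

    rows = []
    for stage in STAGES:
        if medical_by_stage is not None:
            med_stage = medical_by_stage.loc[year, stage]
        elif projection.by_stage is not None:
            sel = projection.by_stage
            med_stage = float(
                sel.loc[(sel["year"] == year) & (sel["stage"] == stage),
                        "medical_eur"].iloc[0]
            )
        else:
            raise ValueError("stage-split medical costs required for per-person view")
        if stage_tot[stage] <= 0.0:
            raise ZeroDivisionError(
                f"no {stage}-stage patients in {year}: per-person cost undefined"
            )
        med_pp = med_stage / stage_tot[stage]
        rows.append([stage, med_pp, nm_pp, med_pp + nm_pp])
    med_pp_all = med_total / total_ad
    rows.append(["all", med_pp_all, nm_pp, med_pp_all + nm_pp])
    return pd.DataFrame(
        rows, columns=["stage", "medical_eur_pp", "nonmedical_eur_pp", "total_eur_pp"]
    ).set_index("stage")


def project_costs(
    trajectory: list[ADState],
    unit_costs: MedicalUnitCostTable,
    shares: TreatedShareTable,
    residential: list[ResidentialService],
    nonresidential: list[NonResidentialService],
    base_year: int | None = None,
    region: str = "",
) -> tuple[CostProjection, pd.DataFrame]:
    """Full cost pipeline: medical + growth-indexed non-medical streams.

    Returns the combined :class:`CostProjection` and the stage-split medical
    frame (needed for per-person figures).
    """
    med = medical_costs(trajectory, unit_costs, shares)
    idx = growth_index(trajectory, base_year)
    nonmed = nonmedical_costs(residential, nonresidential, idx)
    stage_counts = pd.DataFrame(
        {stage: [s.stage_totals()[i] for s in trajectory]
         for i, stage in enumerate(STAGES)},
        index=pd.Index([s.year for s in trajectory], name="year"),
    )
    return aggregate(med, nonmed, stage_counts, region=region), med
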