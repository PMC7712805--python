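#!/usr/bin/env python
"""Attach the direct-cost model to the simulated AD trajectory.

Medical costs follow treated head-counts at constant per-treated-patient
unit rates; non-medical (social-care) costs scale the base-year inventory
cost (bed-days and FTE-months weighted by AD utilisation) with the growth
of the AD population.  Writes the yearly cost table, the per-person table,
and the run manifest.
"""

from pathlib import Path

from adburden import costs as cm, io as adio
from adburden.population import run_projection

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    config = adio.read_scenario(BASE / "inputs" / "scenario.yaml")
    trajectory = adio.read_trajectory(BASE / "population" / "trajectory.csv",
                                      region=config.region)
    unit, shares, residential, nonres = adio.load_cost_inputs(config)
    cp, med = cm.project_costs(trajectory, unit, shares, residential, nonres,
                               region=config.region)
    out = BASE / "costs"
    files = adio.report(cp, trajectory, out, medical_by_stage=med)

    by_year = cp.by_year
    first, last = by_year.iloc[0], by_year.iloc[-1]
    print(f"direct costs, region {config.region}:")
    print(f"  {by_year.index[0]}: medical {first['medical_eur'] / 1e6:.3f} MEUR"
          f" + non-medical {first['nonmedical_eur'] / 1e6:.3f} MEUR"
          f" = {first['total_eur'] / 1e6:.3f} MEUR")
    print(f"  {by_year.index[-1]}: medical {last['medical_eur'] / 1e6:.3f} MEUR"
          f" + non-medical {last['nonmedical_eur'] / 1e6:.3f} MEUR"
          f" = {last['total_eur'] / 1e6:.3f} MEUR")
    print(f"  growth factor: {last['total_eur'] / first['total_eur']:.2f}x")
    print(f"outputs: {', '.join(str(p) for p in files.values())}")


if __name__ == "__main__":
    main()
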