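"""Generate the synthetic study system.

Builds a 60-site landscape whose covariates follow the assumed causal DAG,
draws a six-group arthropod community from the group-level slope
distributions, simulates a year of monthly detection histories per group,
and writes raw 5-minute logger streams with injected artifacts.

Outputs under results/sim/: site table, covariate rasters, detection
histories (long CSV per group), logger records, and the generating truth.
"""

import json
from pathlib import Path

import numpy as np

from urbanocc import rasters, synthetic

OUT = Path(__file__).resolve().parents[1] / "results" / "sim"
SEED = 20240901

# scaled-down group sizes (same proportions as the full community) keep the
# downstream fits fast while preserving the multi-group structure
GROUP_SIZES_SCALED = {"Phoridae": 27, "Syrphidae": 9, "Tipuloidea": 5,
                      "Drosophilidae": 7, "Mycetophilidae": 6, "Araneae": 6}
LOGGER_DAYS = 30


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    land = synthetic.generate_landscape(n_sites=60, grid_shape=(25, 25),
                                        seed=SEED)
    land.sites.to_csv(OUT / "sites.csv", index=False)
    for name, r in land.rasters.items():
        rasters.write_ascii(r, OUT / f"raster_{name}.asc")
    print(f"landscape: {len(land.sites)} sites on a "
          f"{land.rasters['elevation'].shape} km grid")

    truth_meta = {}
    for g, (group, n) in enumerate(GROUP_SIZES_SCALED.items()):
        predictors = synthetic.ALL_MODEL_TERMS
        truth = synthetic.generate_community(
            n, seed=SEED + 10 + g, predictors=predictors,
            species_names=[f"{group}_{i:03d}" for i in range(1, n + 1)])
        data = synthetic.simulate_detections(
            truth, land, seed=SEED + 100 + g, missing_rate=0.05, group=group)
        data.to_long().to_csv(OUT / f"detections_{group}.csv", index=False)
        true_params = truth.species_slopes.copy()
        true_params["intercept_psi"] = truth.species_intercepts_psi
        true_params.to_csv(OUT / f"true_slopes_{group}.csv")
        truth_meta[group] = {
            "n_species": n,
            "psi0": truth.psi0,
            "mu_slope": truth.mu_slope,
            "sigma_slope": truth.sigma_slope,
            "p0": truth.p0, "p_month2": truth.p_month2,
            "naive_occupancy": float(np.nan_to_num(data.y).max(2).mean()),
        }
        print(f"{group}: {n} species, "
              f"{int(np.nansum(data.y))} detections, "
              f"naive occupancy {truth_meta[group]['naive_occupancy']:.2f}")

    streams = synthetic.generate_logger_streams(land, days=LOGGER_DAYS,
                                                seed=SEED + 500)
    streams.records.to_csv(OUT / "logger_records.csv", index=False)
    truth_meta["loggers"] = {
        "days": LOGGER_DAYS,
        "hot_site": streams.truth.get("hot_site"),
        "fahrenheit_sites": streams.truth["fahrenheit_sites"],
        "n_spikes": streams.truth["n_spikes"],
    }
    with open(OUT / "truth.json", "w") as fh:
        json.dump(truth_meta, fh, indent=1, default=str)
    print(f"loggers: {len(streams.records)} raw records over {LOGGER_DAYS} "
          f"days; hot site {streams.truth.get('hot_site')}, "
          f"{len(streams.truth['fahrenheit_sites'])} Fahrenheit sites")


if __name__ == "__main__":
    main()
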