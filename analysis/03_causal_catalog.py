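"""Validate the per-group DAGs against the site data and build the model
catalog.

Tests every DAG-implied conditional independency with partial correlations
on the simulated site covariates, reports violations, derives the minimal
backdoor adjustment set per exposure, and writes the catalog of
single-exposure occupancy model specifications (37 entries for the six
default groups).
"""

import json
from pathlib import Path

import pandas as pd

from urbanocc import causal
from urbanocc.synthetic import DEFAULT_SEM_COEFS

SIM = Path(__file__).resolve().parents[1] / "results" / "sim"
OUT = Path(__file__).resolve().parents[1] / "results" / "causal"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    sites = pd.read_csv(SIM / "sites.csv")

    # the Phoridae DAG carries every covariate incl. relative humidity
    dag = causal.default_dag("Phoridae").without_outcome()
    dag.to_edgelist_csv(OUT / "dag_covariates.csv")
    (OUT / "dag_covariates.dot").write_text(dag.to_dot())
    implied = causal.implied_independencies(dag)
    violations = causal.test_consistency(dag, sites, alpha=0.05)
    print(f"DAG: {len(dag.edges)} edges, {len(implied)} implied "
          f"independencies, {len(violations)} flagged at alpha=0.05 on the "
          f"60 sites")
    print("  (site covariates are spatially autocorrelated, so the "
          "partial-correlation test runs anti-conservative here; the same "
          "test on exchangeable draws from the SEM is calibrated:)")
    iid = causal.simulate_linear_sem(dag, n=2000, coefs=DEFAULT_SEM_COEFS,
                                     seed=1)
    iid_viol = causal.test_consistency(dag, iid, alpha=0.05)
    print(f"  iid SEM (n=2000): {len(iid_viol)}/{len(implied)} flagged "
          f"(~{0.05 * len(implied):.1f} expected by chance)")
    for x, y, z, p in violations:
        print(f"  site data: {x} _||_ {y} | {sorted(z)} flagged (p={p:.4f})")

    catalog = causal.build_catalog()
    causal.catalog_to_json(catalog, OUT / "catalog.json")
    counts = pd.Series([m.group for m in catalog]).value_counts()
    print(f"catalog: {len(catalog)} model specifications "
          f"({dict(counts.sort_index())})")
    for m in catalog:
        if m.group == "Phoridae":
            print(f"  Phoridae {m.name}: adjust for {list(m.adjustment) or 'nothing'}")

    with open(OUT / "consistency.json", "w") as fh:
        json.dump({
            "n_implied": len(implied),
            "n_violated": len(violations),
            "violations": [
                {"x": x, "y": y, "given": sorted(z), "p": p}
                for x, y, z, p in violations],
        }, fh, indent=1)


if __name__ == "__main__":
    main()
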