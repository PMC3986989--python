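#!/usr/bin/env python
"""Assess human health risk per zone via the three-pathway exposure model.

Computes the non-carcinogenic hazard index (child and adult receptors)
and the age-adjusted total carcinogenic risk for Cd, Cr, Ni and Pb from
zone-mean concentrations.  Writes results/health.csv and prints the
right-of-way vs distance comparison.
"""

from pathlib import Path

import soilrisk as sr

ROOT = Path(__file__).resolve().parents[1]
ROW = ("trench", "working", "piling")

if __name__ == "__main__":
    table = sr.load_samples(ROOT / "results" / "synthetic_samples.csv")
    _, _, exposure, tox = sr.default_parameters(None)
    prof = sr.health_profile(table, exposure, tox)
    prof.to_csv(ROOT / "results" / "health.csv", index=False,
                float_format="%.6g")
    print(f"wrote {ROOT / 'results' / 'health.csv'}")
    for (site, receptor), g in prof.groupby(["site", "receptor"]):
        z = g.set_index("zone")
        row = z.loc[list(ROW), "HI"].mean()
        d20 = z[z["distance_m"] == 20]["HI"].mean()
        d50 = z[z["distance_m"] == 50]["HI"].mean()
        print(f"  {site} {receptor}: HI RoW {row:.3g} | 20 m {d20:.3g} "
              f"| 50 m {d50:.3g}")
    cancer = prof[prof["receptor"] == "child"]
    for site, g in cancer.groupby("site"):
        z = g.set_index("zone")
        print(f"  {site} total cancer risk: trench "
              f"{z.loc['trench', 'total_risk']:.3g} vs 50 m "
              f"{z[z['distance_m'] == 50]['total_risk'].mean():.3g}")
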