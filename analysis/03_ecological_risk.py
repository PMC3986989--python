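#!/usr/bin/env python
"""Score each zone on the Hakanson potential ecological risk index.

RI sums toxicity-weighted pollution factors over the six metals
(background soil scores RI = 48).  Writes results/ri.csv and prints the
zone ranking, expected to decline trench > working > piling > 20 m >
50 m.
"""

from pathlib import Path

import soilrisk as sr

ROOT = Path(__file__).resolve().parents[1]

if __name__ == "__main__":
    table = sr.load_samples(ROOT / "results" / "synthetic_samples.csv")
    backgrounds = {s: sr.default_parameters(s)[0] for s in ("Site1", "Site2")}
    _, T, _, _ = sr.default_parameters(None)
    prof = sr.ri_profile(table, backgrounds, T)
    prof.to_csv(ROOT / "results" / "ri.csv", index=False, float_format="%.6g")
    print(f"wrote {ROOT / 'results' / 'ri.csv'}")
    for site, g in prof.groupby("site"):
        ranked = g.sort_values("RI", ascending=False)
        print(f"  {site} RI ranking:")
        for _, row in ranked.iterrows():
            print(f"    {row['zone']:<10} RI={row['RI']:7.1f}  "
                  f"{row['category']}")
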