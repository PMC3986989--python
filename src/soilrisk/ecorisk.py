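"""Hakanson potential ecological risk index.

For each metal ``i`` the pollution factor is the background-normalized
concentration, the monomial risk factor weights it by a metal-specific
toxicity factor, and the risk index sums over the six metals:

    f_i  = C_i / B_i
    E_i  = T_i * f_i
    RI   = sum_i E_i

With the default toxicity factors (Cd 30, Cu/Ni/Pb 5, Cr 2, Zn 1) soil
exactly at background gives RI = 48.  RI is graded on the adjusted
criteria: RI <= 50 low, 50 < RI <= 100 moderate, 100 < RI <= 200
considerable, RI > 200 high pollution.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datamodel import (METALS, ZONE_DISTANCE, BackgroundSet, ParameterError,
                        ToxicityFactorSet, ValidationError)

#: RI category upper bounds (half-open intervals, upper bound included).
RI_CATEGORIES: tuple[tuple[float, str], ...] = (
    (50.0, "low"),
    (100.0, "moderate"),
    (200.0, "considerable"),
    (float("inf"), "high"),
)


@dataclass
class EcoRiskResult:
    site: str
    zone: str
    f: dict[str, float]
    E: dict[str, float]
    RI: float
    category: str


def pollution_factor(C: float, B: float) -> float:
    """Pollution factor f = C/B."""
    if B <= 0:
        raise ParameterError(f"background must be > 0, got {B}")
    if C < 0:
        raise ValidationError(f"concentration must be >= 0, got {C}")
    return C / B


def monomial_risk(f: float, metal: str, T: ToxicityFactorSet) -> float:
    """Monomial ecological risk factor E = T_m * f."""
    if f < 0:
        raise ValidationError(f"pollution factor must be >= 0, got {f}")
    return T[metal] * f


def risk_index(E: dict[str, float]) -> float:
    """Potential ecological risk index: the sum of monomial risk factors."""
    if not E:
        raise ParameterError("empty risk-factor map")
    if any(v < 0 for v in E.values()):
        raise ValidationError("risk factors must be >= 0")
    return float(sum(E.values()))


def classify_ri(RI: float) -> str:
    """Pollution category for an RI value."""
    if RI < 0:
        raise ValidationError(f"RI must be >= 0, got {RI}")
    for bound, cat in RI_CATEGORIES:
        if RI <= bound:
            return cat
    raise AssertionError("unreachable")  # pragma: no cover


def ri_profile(samples: pd.DataFrame,
               backgrounds: BackgroundSet | dict[str, BackgroundSet],
               T: ToxicityFactorSet,
               per_sample: bool = False) -> pd.DataFrame:
    """Zone-level ecological risk profile per site.

    Zone values apply the index to zone-mean concentrations; because every
    term is linear in concentration this equals the mean of per-sample RI.
    With ``per_sample=True`` a per-sample table is returned instead (for
    use in the between-zone ANOVA).

    Returns a DataFrame with columns ``site, zone, distance_m, RI,
    category, E_<metal>..., f_<metal>...`` ordered by nominal distance.
    """
    if samples.empty:
        raise ValidationError("empty sample table")

    rows = []
    group_cols = ["site", "transect", "zone"] if per_sample else ["site",
                                                                  "zone"]
    for key, df in samples.groupby(group_cols, sort=False):
        site = key[0]
        zone = key[-1]
        bg = backgrounds[site] if isinstance(backgrounds, dict) else backgrounds
        f = {m: pollution_factor(float(df[m].mean()), bg[m]) for m in METALS}
        E = {m: monomial_risk(f[m], m, T) for m in METALS}
        RI = risk_index(E)
        row = {"site": site, "zone": zone,
               "distance_m": ZONE_DISTANCE[zone],
               "RI": RI, "category": classify_ri(RI)}
        if per_sample:
            row["transect"] = key[1]
        row.update({f"E_{m}": E[m] for m in METALS})
        row.update({f"f_{m}": f[m] for m in METALS})
        rows.append(row)

    out = pd.DataFrame(rows)
    out = out.sort_values(["site", "distance_m", "zone"],
                          kind="stable").reset_index(drop=True)
    lead = ["site"] + (["transect"] if per_sample else []) + [
        "zone", "distance_m", "RI", "category"]
    return out[lead + [f"E_{m}" for m in METALS] +
               [f"f_{m}" for m in METALS]]
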