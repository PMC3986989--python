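"""Three-pathway human health risk: doses, hazard quotients, cancer risk.

Exposure to soil metals is modelled through direct ingestion, inhalation
of resuspended particulates, and dermal contact, for child and adult
receptors, following the USDOE RAIS / USEPA RAGS conventions.  With C the
soil concentration (mg/kg), the non-carcinogenic dose terms are

    CDI_ing    = C * IngR * EF * ED / (BW * AT_nc) * 1e-6       [mg/kg/d]
    EC_inh     = C * (ET * EF * ED) / (PEF * 24 * AT_nc)        [mg/m3]
    CDI_dermal = C * SA * AF * ABS_d * EF * ED / (BW * AT_nc) * 1e-6

(the single factor 1e-6 kg/mg converts the ingested/adhered soil mass),
and the hazard quotients divide by the route-matched toxicity value:

    HQ_ing = CDI_ing / RfD_ing        HQ_inh = EC_inh / RfC_inh
    HQ_dermal = CDI_dermal / (RfD_ing * ABS_GI)
    HI = sum of HQ over routes (and, in zone profiles, over metals)

Carcinogenic risk uses lifetime-averaged, age-adjusted doses.  The
age-adjusted ingestion and dermal contact factors time-weight childhood
and the remaining adult years:

    IR_adj  = ED_c*IngR_c/BW_c + (ED_a - ED_c)*IngR_a/BW_a   [mg*year/kg/d]
    DFS_adj = ED_c*SA_c*AF_c/BW_c + (ED_a - ED_c)*SA_a*AF_a/BW_a

(113 and 362.4 with the default exposure factors).  Risks per route are

    Risk_ing    = C * IR_adj  * EF / AT_ca * 1e-6 * CSF_ing
    Risk_dermal = C * DFS_ABS * EF / AT_ca * 1e-6 * (CSF_ing / ABS_GI)
    Risk_inh    = C * (1000/PEF) * (ET/24) * EF * ED_inh / AT_ca * IUR

where DFS_ABS folds the age-specific dermal absorption fraction into the
age sum, inhalation converts to ug/m3 to match the inhalation unit risk,
and Total Risk sums over the carcinogens Cd, Cr, Ni and Pb.  A metal ×
route whose toxicity value is unavailable contributes zero and is
reported in ``skipped_routes``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .datamodel import (CARCINOGENS, METALS, ZONE_DISTANCE, ExposureParams,
                        ParameterError, ToxParams, ValidationError)

logger = logging.getLogger("soilrisk")

KG_PER_MG = 1e-6
UG_PER_MG = 1e3

ROUTES = ("ing", "inh", "dermal")


def _check_conc(C: float) -> None:
    if C < 0:
        raise ValidationError(f"concentration must be >= 0, got {C}")


# --------------------------------------------------------------------------
# Non-carcinogenic dose terms
# --------------------------------------------------------------------------

def cdi_ingestion_nc(C: float, receptor: str, p: ExposureParams) -> float:
    """Chronic daily soil ingestion dose (mg/kg/d)."""
    _check_conc(C)
    r = p.receptor(receptor)
    return C * r.IngR * p.EF * r.ED / (r.BW * p.AT_nc(receptor)) * KG_PER_MG


def ec_inhalation_nc(C: float, receptor: str, p: ExposureParams) -> float:
    """Air exposure concentration from soil particulates (mg/m3).

    With ET = 24 h/d this reduces to C * (EF/365) / PEF and is
    receptor-independent (ED cancels against AT_nc).
    """
    _check_conc(C)
    r = p.receptor(receptor)
    return C * p.ET * p.EF * r.ED / (p.PEF * 24.0 * p.AT_nc(receptor))


def cdi_dermal_nc(C: float, receptor: str, p: ExposureParams) -> float:
    """Chronic daily dermally absorbed dose (mg/kg/d)."""
    _check_conc(C)
    r = p.receptor(receptor)
    return (C * r.SA * r.AF * r.ABS_d * p.EF * r.ED
            / (r.BW * p.AT_nc(receptor)) * KG_PER_MG)


# --------------------------------------------------------------------------
# Age-adjusted factors
# --------------------------------------------------------------------------

def age_adjusted_ingestion(p: ExposureParams) -> float:
    """Age-adjusted soil ingestion rate IR_adj (mg*year/kg/d).

    Childhood years use child parameters; the remaining
    ``ED_adult - ED_child`` years use adult parameters.
    """
    c, a = p.child, p.adult
    return c.ED * c.IngR / c.BW + (a.ED - c.ED) * a.IngR / a.BW


def age_adjusted_dermal(p: ExposureParams) -> float:
    """Age-adjusted soil dermal contact factor DFS_adj (mg*year/kg/d).

    Same age-span convention as :func:`age_adjusted_ingestion`; excludes
    the dermal absorption fraction ABS_d.
    """
    c, a = p.child, p.adult
    return c.ED * c.SA * c.AF / c.BW + (a.ED - c.ED) * a.SA * a.AF / a.BW


def dermal_contact_abs(p: ExposureParams,
                       mode: str = "within_sum") -> float:
    """Age-adjusted dermal contact factor including absorption.

    ``within_sum`` (default) applies each receptor's own ABS_d inside the
    age sum; ``child``/``adult`` scale DFS_adj by that single receptor's
    ABS_d instead.
    """
    c, a = p.child, p.adult
    if mode == "within_sum":
        return (c.ED * c.SA * c.AF * c.ABS_d / c.BW
                + (a.ED - c.ED) * a.SA * a.AF * a.ABS_d / a.BW)
    if mode in ("child", "adult"):
        return age_adjusted_dermal(p) * p.receptor(mode).ABS_d
    raise ParameterError(
        f"unknown dermal_cancer_abs mode {mode!r}; "
        "expected within_sum, child or adult")


# --------------------------------------------------------------------------
# Hazard quotients / index
# --------------------------------------------------------------------------

@dataclass
class HazardResult:
    receptor: str
    HQ: dict[tuple[str, str], float]
    HI: float
    skipped_routes: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class CancerResult:
    risk: dict[tuple[str, str], float]
    total_risk: float
    skipped_routes: list[tuple[str, str]] = field(default_factory=list)


def hazard_index(conc: dict[str, float], receptor: str, p: ExposureParams,
                 t: ToxParams) -> HazardResult:
    """Non-carcinogenic hazard quotients and their sum HI for one receptor.

    Routes whose reference value is unavailable contribute zero and are
    recorded in ``skipped_routes``; a table with nothing evaluable at all
    is an error.
    """
    HQ: dict[tuple[str, str], float] = {}
    skipped: list[tuple[str, str]] = []
    evaluable = 0
    for metal, C in conc.items():
        if metal not in METALS:
            raise ParameterError(f"unknown metal {metal!r}")
        _check_conc(C)
        mt = t[metal]
        if mt.RfD_ing is not None:
            evaluable += 1
            HQ[(metal, "ing")] = cdi_ingestion_nc(C, receptor, p) / mt.RfD_ing
            HQ[(metal, "dermal")] = (cdi_dermal_nc(C, receptor, p)
                                     / (mt.RfD_ing * mt.ABS_GI))
        else:
            skipped += [(metal, "ing"), (metal, "dermal")]
        if mt.RfC_inh is not None:
            evaluable += 1
            HQ[(metal, "inh")] = ec_inhalation_nc(C, receptor, p) / mt.RfC_inh
        else:
            skipped.append((metal, "inh"))
    if not evaluable:
        raise ParameterError("no metal x route evaluable: all reference "
                             "doses/concentrations missing")
    if skipped:
        logger.info("hazard_index(%s): skipped routes without reference "
                    "values: %s", receptor, skipped)
    return HazardResult(receptor, HQ, float(sum(HQ.values())), skipped)


# --------------------------------------------------------------------------
# Carcinogenic risk
# --------------------------------------------------------------------------

def cancer_risk(conc: dict[str, float], p: ExposureParams, t: ToxParams,
                ed_inh: float | None = None,
                dermal_cancer_abs: str = "within_sum") -> CancerResult:
    """Incremental lifetime cancer risk per carcinogen and route.

    Only the designated carcinogens (Cd, Cr, Ni, Pb) are evaluated.
    ``ed_inh`` is the inhalation exposure duration in years (defaults to
    the adult ED).  Routes lacking a slope factor / unit risk are skipped.
    """
    if ed_inh is None:
        ed_inh = p.adult.ED
    ir_adj = age_adjusted_ingestion(p)
    dfs_abs = dermal_contact_abs(p, dermal_cancer_abs)

    risk: dict[tuple[str, str], float] = {}
    skipped: list[tuple[str, str]] = []
    for metal in CARCINOGENS:
        if metal not in conc:
            continue
        C = conc[metal]
        _check_conc(C)
        mt = t[metal]
        if mt.CSF_ing is not None:
            risk[(metal, "ing")] = (C * ir_adj * p.EF / p.AT_ca
                                    * KG_PER_MG * mt.CSF_ing)
            risk[(metal, "dermal")] = (C * dfs_abs * p.EF / p.AT_ca
                                       * KG_PER_MG
                                       * (mt.CSF_ing / mt.ABS_GI))
        else:
            skipped += [(metal, "ing"), (metal, "dermal")]
        if mt.IUR is not None:
            risk[(metal, "inh")] = (C * (UG_PER_MG / p.PEF) * (p.ET / 24.0)
                                    * p.EF * ed_inh / p.AT_ca * mt.IUR)
        else:
            skipped.append((metal, "inh"))
    if skipped:
        logger.info("cancer_risk: skipped routes without slope factors: %s",
                    skipped)
    return CancerResult(risk, float(sum(risk.values())), skipped)


# --------------------------------------------------------------------------
# Zone profiles
# --------------------------------------------------------------------------

def health_profile(samples: pd.DataFrame, p: ExposureParams, t: ToxParams,
                   ed_inh: float | None = None,
                   dermal_cancer_abs: str = "within_sum") -> pd.DataFrame:
    """Zone-level health risk profile from zone-mean concentrations.

    Returns one row per (site, zone, receptor) with the summed hazard
    index HI, per-metal-route hazard quotients, the total carcinogenic
    risk and its per-metal-route components (the cancer columns are
    age-adjusted and therefore identical for both receptors), ordered by
    nominal distance.
    """
    if samples.empty:
        raise ValidationError("empty sample table")

    rows = []
    for (site, zone), df in samples.groupby(["site", "zone"], sort=False):
        conc = {m: float(df[m].mean()) for m in METALS}
        ca = cancer_risk(conc, p, t, ed_inh=ed_inh,
                         dermal_cancer_abs=dermal_cancer_abs)
        for receptor in ("child", "adult"):
            hz = hazard_index(conc, receptor, p, t)
            row = {"site": site, "zone": zone,
                   "distance_m": ZONE_DISTANCE[zone],
                   "receptor": receptor, "HI": hz.HI,
                   "total_risk": ca.total_risk}
            for (m, route), v in hz.HQ.items():
                row[f"HQ_{m}_{route}"] = v
            for (m, route), v in ca.risk.items():
                row[f"risk_{m}_{route}"] = v
            rows.append(row)

    out = pd.DataFrame(rows)
    out = out.sort_values(["site", "distance_m", "zone", "receptor"],
                          kind="stable").reset_index(drop=True)
    lead = ["site", "zone", "distance_m", "receptor", "HI", "total_risk"]
    rest = [c for c in out.columns if c not in lead]
    return out[lead + rest]
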