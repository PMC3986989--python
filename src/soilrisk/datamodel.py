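"""Domain types, packaged parameter fixtures and input validation.

The package assesses six heavy metals in agricultural topsoil: Cd, Cr, Cu,
Ni, Pb and Zn.  Sampling follows a transect design around a linear
construction corridor (the pipeline right-of-way): each transect crosses
seven zones — the trench (0 m), the working zone and the piling area
(both 10 m from the trench, on opposite sides), and paired plots at 20 m
and 50 m on either side.

Three parameter families are packaged as fixtures and can be overridden
from a TOML config file:

* soil background concentrations per site (mg/kg dry soil), together with
  the Chinese Environmental Quality Standard Grade I screening values;
* Hakanson toxicity factors for the ecological risk index;
* exposure factors (child/adult receptors) and per-metal toxicological
  values (RfD, RfC, ABS_GI, CSF, IUR) for the three-pathway human health
  risk model.

All concentrations are dry-weight mg/kg; no moisture correction is
applied.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field, fields
from io import StringIO
from pathlib import Path
from typing import Mapping

import pandas as pd

try:  # py3.11+
    import tomllib
except ModuleNotFoundError:  # pragma: no cover
    import tomli as tomllib  # type: ignore

logger = logging.getLogger("soilrisk")

#: The six metals recognized throughout the package, in canonical order.
METALS: tuple[str, ...] = ("Cd", "Cr", "Cu", "Ni", "Pb", "Zn")

#: Carcinogens evaluated in the cancer-risk model.
CARCINOGENS: tuple[str, ...] = ("Cd", "Cr", "Ni", "Pb")

#: Zone label -> nominal distance from the trench centreline (m).
ZONE_DISTANCE: dict[str, float] = {
    "trench": 0.0,
    "working": 10.0,
    "piling": 10.0,
    "d20_side1": 20.0,
    "d20_side2": 20.0,
    "d50_side1": 50.0,
    "d50_side2": 50.0,
}

ZONES: tuple[str, ...] = tuple(ZONE_DISTANCE)

# Compass-direction labels normalized to side-agnostic zone names.  The
# analyses only ever group by distance, so east/west (Site 1) and
# north/south (Site 2) collapse onto side1/side2; the original label is
# retained as free-text metadata.
ZONE_ALIASES: dict[str, str] = {
    "e20": "d20_side1", "w20": "d20_side2",
    "n20": "d20_side1", "s20": "d20_side2",
    "e50": "d50_side1", "w50": "d50_side2",
    "n50": "d50_side1", "s50": "d50_side2",
}

SAMPLE_COLUMNS = ("site", "transect", "zone", "distance_m") + METALS


class SoilRiskError(Exception):
    """Base class for package errors."""


class ValidationError(SoilRiskError):
    """Malformed or inconsistent input data."""


class ParameterError(SoilRiskError):
    """Invalid or missing model parameter."""


def _check_metal_map(values: Mapping[str, float], what: str,
                     positive: bool = True) -> dict[str, float]:
    missing = [m for m in METALS if m not in values]
    if missing:
        raise ParameterError(f"{what} missing metals: {', '.join(missing)}")
    unknown = [m for m in values if m not in METALS]
    if unknown:
        raise ParameterError(
            f"{what} has unknown metals: {', '.join(unknown)}; "
            f"recognized: {', '.join(METALS)}")
    out = {m: float(values[m]) for m in METALS}
    for m, v in out.items():
        if positive and not v > 0:
            raise ParameterError(f"{what}[{m}] must be > 0, got {v}")
        if not positive and v < 0:
            raise ParameterError(f"{what}[{m}] must be >= 0, got {v}")
    return out


@dataclass
class BackgroundSet:
    """Per-metal background concentrations (mg/kg dry soil)."""

    values: dict[str, float]
    provenance: str = "user"  # site_local | average_shale | user

    def __post_init__(self) -> None:
        self.values = _check_metal_map(self.values, "backgrounds")
        if self.provenance not in ("site_local", "average_shale", "user"):
            raise ParameterError(
                f"unknown background provenance {self.provenance!r}")

    def __getitem__(self, metal: str) -> float:
        return self.values[metal]


@dataclass
class ToxicityFactorSet:
    """Hakanson metal toxicity factors T_i (dimensionless)."""

    T: dict[str, float]

    def __post_init__(self) -> None:
        self.T = _check_metal_map(self.T, "toxicity factors")

    def __getitem__(self, metal: str) -> float:
        return self.T[metal]


@dataclass
class ReceptorExposure:
    """Receptor-specific exposure factors."""

    ABS_d: float   # dermal absorption factor (-)
    AF: float      # soil-to-skin adherence factor (mg/cm2)
    BW: float      # body weight (kg)
    ED: float      # exposure duration (year)
    IngR: float    # soil ingestion rate (mg/d)
    SA: float      # exposed skin surface area (cm2/event)


@dataclass
class ExposureParams:
    """Exposure factors for the three-pathway soil exposure model.

    ``child``/``adult`` hold the receptor-specific factors; the shared
    block carries exposure frequency EF (d/year), exposure time ET (h/d),
    lifetime LT (year) and the soil-to-air particulate emission factor
    PEF (m3/kg).  Averaging times and the age-adjusted ingestion/dermal
    factors are derived, never stored.
    """

    child: ReceptorExposure
    adult: ReceptorExposure
    EF: float = 350.0
    ET: float = 24.0
    LT: float = 72.0
    PEF: float = 1.36e9

    def receptor(self, name: str) -> ReceptorExposure:
        if name not in ("child", "adult"):
            raise ParameterError(
                f"unknown receptor {name!r}; expected 'child' or 'adult'")
        return getattr(self, name)

    def AT_nc(self, receptor: str) -> float:
        """Non-carcinogenic averaging time (d): ED x 365."""
        return self.receptor(receptor).ED * 365.0

    @property
    def AT_ca(self) -> float:
        """Carcinogenic averaging time (d): LT x 365."""
        return self.LT * 365.0


@dataclass
class MetalTox:
    """Toxicological values for one metal; ``None`` marks a route that
    cannot be evaluated (a "--" cell in the source compilation)."""

    RfD_ing: float | None = None   # oral reference dose (mg/kg/d)
    RfC_inh: float | None = None   # inhalation reference conc. (mg/m3)
    ABS_GI: float = 1.0            # gastrointestinal absorption (-)
    CSF_ing: float | None = None   # oral cancer slope factor ((mg/kg/d)^-1)
    IUR: float | None = None       # inhalation unit risk ((ug/m3)^-1)


@dataclass
class ToxParams:
    """Per-metal toxicological parameter collection."""

    metals: dict[str, MetalTox]

    def __post_init__(self) -> None:
        missing = [m for m in METALS if m not in self.metals]
        if missing:
            raise ParameterError(
                f"toxicological table missing metals: {', '.join(missing)}")

    def __getitem__(self, metal: str) -> MetalTox:
        if metal not in self.metals:
            raise ParameterError(f"no toxicological data for {metal!r}")
        return self.metals[metal]


# --------------------------------------------------------------------------
# Packaged fixtures
# --------------------------------------------------------------------------

#: Site-local soil background concentrations (mg/kg), per study site.
SITE_BACKGROUNDS: dict[str, dict[str, float]] = {
    "Site1": {"Cd": 0.107, "Cr": 57.5, "Cu": 23.0,
              "Ni": 29.3, "Pb": 16.8, "Zn": 67.9},
    "Site2": {"Cd": 0.092, "Cr": 64.5, "Cu": 22.4,
              "Ni": 26.5, "Pb": 25.1, "Zn": 71.1},
}

#: Chinese Environmental Quality Standard, Grade I screening values (mg/kg).
GRADE_I_SCREENING: dict[str, float] = {
    "Cd": 0.2, "Cr": 90.0, "Cu": 35.0, "Ni": 40.0, "Pb": 35.0, "Zn": 100.0,
}

#: Hakanson toxicity factors: Cd > Cu = Ni = Pb > Cr > Zn.
DEFAULT_TOXICITY_FACTORS: dict[str, float] = {
    "Cd": 30.0, "Cu": 5.0, "Ni": 5.0, "Pb": 5.0, "Cr": 2.0, "Zn": 1.0,
}

_DEFAULT_EXPOSURE = ExposureParams(
    child=ReceptorExposure(ABS_d=0.03, AF=0.2, BW=16.2, ED=6.0,
                           IngR=200.0, SA=2800.0),
    adult=ReceptorExposure(ABS_d=0.001, AF=0.07, BW=61.8, ED=30.0,
                           IngR=100.0, SA=5700.0),
    EF=350.0, ET=24.0, LT=72.0, PEF=1.36e9,
)

_DEFAULT_TOX = ToxParams(metals={
    "Cd": MetalTox(RfD_ing=1.0e-3, RfC_inh=1.0e-5, ABS_GI=0.025,
                   CSF_ing=None, IUR=1.8e-3),
    "Cr": MetalTox(RfD_ing=3.0e-3, RfC_inh=None, ABS_GI=0.013,
                   CSF_ing=None, IUR=1.2e-2),
    "Cu": MetalTox(RfD_ing=4.0e-2, RfC_inh=None, ABS_GI=1.0,
                   CSF_ing=None, IUR=None),
    "Ni": MetalTox(RfD_ing=2.0e-2, RfC_inh=9.0e-5, ABS_GI=0.04,
                   CSF_ing=None, IUR=2.6e-4),
    "Pb": MetalTox(RfD_ing=3.5e-3, RfC_inh=None, ABS_GI=1.0,
                   CSF_ing=8.5e-3, IUR=1.2e-5),
    "Zn": MetalTox(RfD_ing=3.0e-1, RfC_inh=None, ABS_GI=1.0,
                   CSF_ing=None, IUR=None),
})


def default_parameters(site: str | None = None,
                       ) -> tuple[BackgroundSet | None, ToxicityFactorSet,
                                  ExposureParams, ToxParams]:
    """Return deep copies of the packaged parameter fixtures.

    Parameters
    ----------
    site
        ``"Site1"`` or ``"Site2"`` to select the packaged site-local
        backgrounds; ``None`` returns no background set (it must then come
        from a config file).

    Returns
    -------
    (BackgroundSet | None, ToxicityFactorSet, ExposureParams, ToxParams)
    """
    if site is None:
        bg = None
    elif site in SITE_BACKGROUNDS:
        bg = BackgroundSet(dict(SITE_BACKGROUNDS[site]),
                           provenance="site_local")
    else:
        raise ParameterError(
            f"unknown site {site!r}; packaged sites: "
            f"{', '.join(sorted(SITE_BACKGROUNDS))}")
    return (bg,
            ToxicityFactorSet(dict(DEFAULT_TOXICITY_FACTORS)),
            copy.deepcopy(_DEFAULT_EXPOSURE),
            copy.deepcopy(_DEFAULT_TOX))


# --------------------------------------------------------------------------
# Sample tables
# --------------------------------------------------------------------------

def normalize_zone(label: str) -> str:
    """Map a zone label (canonical or compass alias) to its canonical name."""
    key = str(label).strip()
    low = key.lower()
    if low in ZONE_DISTANCE:
        return low
    if low in ZONE_ALIASES:
        return ZONE_ALIASES[low]
    raise ValidationError(
        f"unknown zone label {label!r}; allowed: "
        f"{', '.join(ZONES)} (or compass aliases "
        f"{', '.join(sorted(ZONE_ALIASES))})")


def validate_samples(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a sample table.

    Requires the columns ``site, transect, zone`` and the six metals
    (``distance_m`` is recomputed from the zone); normalizes compass zone
    labels, keeps the original under ``zone_label``, and enforces
    non-negative concentrations and unique (site, transect, zone) keys.
    Row order is preserved.
    """
    required = ["site", "transect", "zone", *METALS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {', '.join(missing)}")

    out = df.copy().reset_index(drop=True)
    out["zone_label"] = out["zone"].astype(str)
    zones = []
    for i, lab in enumerate(out["zone"]):
        try:
            zones.append(normalize_zone(lab))
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
    out["zone"] = zones
    out["distance_m"] = [ZONE_DISTANCE[z] for z in zones]

    for m in METALS:
        col = pd.to_numeric(out[m], errors="coerce")
        bad = col.isna()
        if bad.any():
            raise ValidationError(
                f"row {int(bad.idxmax())}: non-numeric {m} concentration")
        neg = col < 0
        if neg.any():
            raise ValidationError(
                f"row {int(neg.idxmax())}: negative {m} concentration "
                f"({col[neg.idxmax()]})")
        out[m] = col.astype(float)

    dup = out.duplicated(subset=["site", "transect", "zone"])
    if dup.any():
        r = int(dup.idxmax())
        raise ValidationError(
            f"row {r}: duplicate (site, transect, zone) key "
            f"({out.at[r, 'site']}, {out.at[r, 'transect']}, "
            f"{out.at[r, 'zone']})")

    return out[["site", "transect", "zone", "zone_label", "distance_m",
                *METALS]]


def load_samples(path: str | Path) -> pd.DataFrame:
    """Read a sample CSV and return the validated table.

    The CSV must carry one header row with columns
    ``site,transect,zone,distance_m,Cd,Cr,Cu,Ni,Pb,Zn`` (UTF-8, decimal
    point).  Compass zone labels (E20, W50, N20, ...) are accepted and
    normalized.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"sample file not found: {path}")
    df = pd.read_csv(path)
    return validate_samples(df)


def write_samples(df: pd.DataFrame, path: str | Path) -> None:
    """Write a validated sample table back to the standard CSV layout."""
    cols = [c for c in SAMPLE_COLUMNS if c in df.columns]
    df.to_csv(path, columns=cols, index=False)


# --------------------------------------------------------------------------
# Config round-trip (TOML)
# --------------------------------------------------------------------------

def _toml_scalar(v: float | str) -> str:
    if isinstance(v, str):
        return f'"{v}"'
    f = float(v)
    if math.isinf(f) or math.isnan(f):
        raise ParameterError("non-finite parameter value")
    return repr(f)


def params_to_toml(backgrounds: Mapping[str, BackgroundSet] | None = None,
                   toxicity: ToxicityFactorSet | None = None,
                   exposure: ExposureParams | None = None,
                   tox: ToxParams | None = None) -> str:
    """Serialize parameter sets to the TOML config dialect.

    ``float(repr(x))`` round-trips exactly, so reloading the emitted text
    reproduces every value bit-for-bit.
    """
    buf = StringIO()
    if backgrounds:
        for site, bg in backgrounds.items():
            buf.write(f"[backgrounds.{site}]\n")
            buf.write(f'provenance = "{bg.provenance}"\n')
            for m in METALS:
                buf.write(f"{m} = {_toml_scalar(bg.values[m])}\n")
            buf.write("\n")
    if toxicity is not None:
        buf.write("[toxicity_factors]\n")
        for m in METALS:
            buf.write(f"{m} = {_toml_scalar(toxicity.T[m])}\n")
        buf.write("\n")
    if exposure is not None:
        for r in ("child", "adult"):
            buf.write(f"[exposure.{r}]\n")
            rec = exposure.receptor(r)
            for f_ in fields(rec):
                buf.write(f"{f_.name} = "
                          f"{_toml_scalar(getattr(rec, f_.name))}\n")
            buf.write("\n")
        buf.write("[exposure.shared]\n")
        for k in ("EF", "ET", "LT", "PEF"):
            buf.write(f"{k} = {_toml_scalar(getattr(exposure, k))}\n")
        buf.write("\n")
    if tox is not None:
        for m in METALS:
            buf.write(f"[tox.{m}]\n")
            mt = tox.metals[m]
            for f_ in fields(mt):
                v = getattr(mt, f_.name)
                if v is not None:
                    buf.write(f"{f_.name} = {_toml_scalar(v)}\n")
            buf.write("\n")
    return buf.getvalue()


def load_config(path: str | Path
                ) -> tuple[dict[str, BackgroundSet], ToxicityFactorSet,
                           ExposureParams, ToxParams]:
    """Load a TOML parameter config, falling back to fixtures for absent keys.

    Recognized sections: ``[backgrounds.<site>]``, ``[toxicity_factors]``,
    ``[exposure.child]``, ``[exposure.adult]``, ``[exposure.shared]``,
    ``[tox.<metal>]``.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)

    _, toxicity, exposure, tox = default_parameters(None)

    backgrounds: dict[str, BackgroundSet] = {
        s: BackgroundSet(dict(v), provenance="site_local")
        for s, v in SITE_BACKGROUNDS.items()}
    for site, sect in raw.get("backgrounds", {}).items():
        sect = dict(sect)
        prov = sect.pop("provenance", "user")
        base = dict(SITE_BACKGROUNDS.get(site, {}))
        base.update(sect)
        backgrounds[site] = BackgroundSet(base, provenance=prov)

    if "toxicity_factors" in raw:
        t = dict(DEFAULT_TOXICITY_FACTORS)
        t.update(raw["toxicity_factors"])
        toxicity = ToxicityFactorSet(t)

    exp_raw = raw.get("exposure", {})
    for r in ("child", "adult"):
        rec = exposure.receptor(r)
        for k, v in exp_raw.get(r, {}).items():
            if not hasattr(rec, k):
                raise ParameterError(f"unknown exposure.{r} key {k!r}")
            setattr(rec, k, float(v))
    for k, v in exp_raw.get("shared", {}).items():
        if k not in ("EF", "ET", "LT", "PEF"):
            raise ParameterError(f"unknown exposure.shared key {k!r}")
        setattr(exposure, k, float(v))

    for m, sect in raw.get("tox", {}).items():
        if m not in METALS:
            raise ParameterError(f"unknown metal {m!r} in [tox] section")
        mt = tox.metals[m]
        for k, v in sect.items():
            if not hasattr(mt, k):
                raise ParameterError(f"unknown tox.{m} key {k!r}")
            setattr(mt, k, float(v))

    return backgrounds, toxicity, exposure, tox
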