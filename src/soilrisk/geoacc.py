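"""Geo-accumulation index and Müller seven-class contamination grading.

The geo-accumulation index compares a measured concentration ``C`` against
``1.5 x B``, where ``B`` is a geochemical background and the factor 1.5
absorbs natural background fluctuation and minor anthropogenic input:

    Igeo = log2(C / (1.5 B))

Values are graded into Müller's seven contamination classes (0 =
uncontaminated through 6 = extremely contaminated) on half-open intervals
(k-1, k] for classes 1..5, with Igeo <= 0 in class 0 and Igeo > 5 in
class 6.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (METALS, ZONE_DISTANCE, BackgroundSet, ParameterError,
                        ValidationError)

logger = logging.getLogger("soilrisk")

#: Müller class labels, indexed by class number.
MUELLER_LABELS: tuple[str, ...] = (
    "uncontaminated",
    "uncontaminated to moderately contaminated",
    "moderately contaminated",
    "moderately to heavily contaminated",
    "heavily contaminated",
    "heavily to extremely contaminated",
    "extremely contaminated",
)


@dataclass
class IgeoResult:
    site: str
    zone: str
    metal: str
    igeo: float
    mueller_class: int
    class_label: str
    n_samples: int


def igeo(C: float, B: float) -> float:
    """Geo-accumulation index log2(C / (1.5 B)).

    ``C = 0`` returns ``-inf`` (flagged non-finite downstream); ``B <= 0``
    is a parameter error.
    """
    if B <= 0:
        raise ParameterError(f"background must be > 0, got {B}")
    if C < 0:
        raise ValidationError(f"concentration must be >= 0, got {C}")
    if C == 0:
        return float("-inf")
    return math.log2(C / (1.5 * B))


def classify_igeo(value: float) -> tuple[int, str]:
    """Müller class (0-6) and label for a geo-accumulation index value.

    Total on the extended reals: ``-inf`` falls in class 0, values above 5
    in class 6; interior classes use half-open intervals (k-1, k].
    """
    if math.isnan(value):
        raise ParameterError("cannot classify NaN index value")
    if value <= 0:
        k = 0
    elif value > 5:
        k = 6
    else:
        k = int(math.ceil(value))
    return k, MUELLER_LABELS[k]


def igeo_profile(samples: pd.DataFrame,
                 backgrounds: BackgroundSet | dict[str, BackgroundSet],
                 aggregation: str = "log_mean") -> pd.DataFrame:
    """Zone-level geo-accumulation profile per site and metal.

    Parameters
    ----------
    samples
        Validated sample table (see :func:`soilrisk.datamodel.load_samples`).
    backgrounds
        One background set applied to every site, or a mapping
        ``site -> BackgroundSet``.
    aggregation
        ``"log_mean"`` (default) averages per-sample index values over the
        transect replicates of a zone; ``"mean_conc"`` applies the index to
        the zone-mean concentration instead.

    Returns
    -------
    DataFrame with columns ``site, zone, distance_m, metal, igeo, class,
    label, n_samples``, ordered by zone distance then metal.  Samples with
    a non-finite index (zero concentration) are excluded from the zone
    mean with a logged notice.
    """
    if samples.empty:
        raise ValidationError("empty sample table")
    if aggregation not in ("log_mean", "mean_conc"):
        raise ParameterError(
            f"unknown igeo aggregation {aggregation!r}; "
            "expected 'log_mean' or 'mean_conc'")

    rows: list[IgeoResult] = []
    for site, site_df in samples.groupby("site", sort=True):
        bg = backgrounds[site] if isinstance(backgrounds, dict) else backgrounds
        for zone, zdf in site_df.groupby("zone", sort=False):
            if zdf.empty:  # pragma: no cover - groupby never yields empty
                continue
            for metal in METALS:
                conc = zdf[metal].to_numpy(dtype=float)
                if aggregation == "mean_conc":
                    val = igeo(float(conc.mean()), bg[metal])
                else:
                    per = np.array([igeo(c, bg[metal]) for c in conc])
                    finite = np.isfinite(per)
                    if not finite.all():
                        logger.warning(
                            "site %s zone %s metal %s: %d zero "
                            "concentration(s) excluded from Igeo mean",
                            site, zone, metal, int((~finite).sum()))
                    per = per[finite]
                    val = float(per.mean()) if per.size else float("-inf")
                k, label = classify_igeo(val)
                rows.append(IgeoResult(str(site), zone, metal, val, k, label,
                                       len(zdf)))

    out = pd.DataFrame([r.__dict__ for r in rows])
    out = out.rename(columns={"mueller_class": "class",
                              "class_label": "label"})
    out["distance_m"] = out["zone"].map(ZONE_DISTANCE)
    out["metal"] = pd.Categorical(out["metal"], categories=METALS,
                                  ordered=True)
    out = out.sort_values(["site", "distance_m", "zone", "metal"],
                          kind="stable").reset_index(drop=True)
    out["metal"] = out["metal"].astype(str)
    return out[["site", "zone", "distance_m", "metal", "igeo", "class",
                "label", "n_samples"]]
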