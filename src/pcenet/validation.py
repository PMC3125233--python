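"""Modeled-vs-measured comparison of water-sample PCE concentrations.

Historical tap-water samples come with a detection limit; non-detects are
substituted (default: half the 0.5 ug/L detection limit) before analysis.
Agreement between modeled point concentrations and measurements is
summarized by the Spearman rank correlation (ranks are what the relative
dose model is meant to preserve) and by ordinary least squares on the
natural-log concentrations (the raw scale is heavily right-skewed), giving
R^2, slope and intercept.  Comparisons can be stratified on sampling and
network characteristics (flow tertile, position along pipe, season,
fixture, personnel, town, liner installation era, configuration
complexity) to see where the model does better or worse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

logger = logging.getLogger(__name__)

DETECTION_LIMIT = 0.5  # ug/L

STRATUM_KEYS = ["flow_tertile", "position", "season", "fixture",
                "personnel", "town", "install_era", "complexity"]


@dataclass(frozen=True)
class ComparisonResult:
    """Agreement summary between modeled and measured concentrations."""

    n: int
    spearman_rho: float
    spearman_p: float
    r2: float
    slope: float
    intercept: float
    flagged: bool = False  # True when a correlation was undefined


def substitute_nondetects(measured, nondetect, detection_limit: float = DETECTION_LIMIT,
                          rule="half_dl") -> np.ndarray:
    """Replace non-detects with a substitution value.

    ``rule`` is ``"half_dl"`` (default; DL/2), ``"dl"`` (the detection limit
    itself) or a callable mapping the detection limit to the value.
    """
    if detection_limit <= 0:
        raise ParameterError("detection limit must be positive")
    if callable(rule):
        value = float(rule(detection_limit))
    elif rule == "half_dl":
        value = detection_limit / 2.0
    elif rule == "dl":
        value = detection_limit
    else:
        raise ParameterError(f"unknown non-detect rule {rule!r}")
    m = np.asarray(measured, dtype=float)
    nd = np.asarray(nondetect, dtype=bool)
    return np.where(nd, value, m)


def compare(modeled, measured) -> ComparisonResult:
    """Spearman correlation on raw values; OLS on ln-transformed pairs."""
    x = np.asarray(modeled, dtype=float)
    y = np.asarray(measured, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("modeled and measured must have equal length")
    n = x.size
    if n < 3:
        raise ParameterError("need at least 3 paired samples")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ParameterError("all values must be positive "
                             "(substitute non-detects first)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero variance: correlation undefined")
        return ComparisonResult(n, float("nan"), float("nan"), float("nan"),
                                float("nan"), float("nan"), flagged=True)
    rho, p = stats.spearmanr(x, y)
    reg = stats.linregress(np.log(x), np.log(y))
    return ComparisonResult(n=n, spearman_rho=float(rho),
                            spearman_p=float(p),
                            r2=float(reg.rvalue ** 2),
                            slope=float(reg.slope),
                            intercept=float(reg.intercept))


def stratified_compare(samples: pd.DataFrame, modeled_col: str = "modeled",
                       measured_col: str = "measured_sub",
                       keys=STRATUM_KEYS) -> pd.DataFrame:
    """One :func:`compare` per stratum level per key; small strata skipped.

    ``samples`` is a sample table that already carries the modeled and
    (substituted) measured columns plus the stratum label columns.
    """
    rows = []
    for key in keys:
        if key not in samples.columns:
            raise ParameterError(f"unknown stratum key {key!r}")
        for level, grp in samples.groupby(key, observed=True):
            if len(grp) < 3:
                logger.info("stratum %s=%s has n=%d < 3; skipped",
                            key, level, len(grp))
                rows.append({"key": key, "level": level, "n": len(grp),
                             "skipped": True})
                continue
            res = compare(grp[modeled_col], grp[measured_col])
            rows.append({"key": key, "level": level, "n": res.n,
                         "skipped": False, "spearman_rho": res.spearman_rho,
                         "spearman_p": res.spearman_p, "r2": res.r2,
                         "slope": res.slope, "intercept": res.intercept,
                         "flagged": res.flagged})
    return pd.DataFrame(rows)
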