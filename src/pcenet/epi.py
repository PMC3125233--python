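"""Case-control association analysis: odds ratios, confounder screening,
exposure-response smoothing and paired comparison of exposure vectors.

Crude odds ratios come from 2x2 tables with Woolf (log-OR Wald) 95%
intervals; adjusted odds ratios come from maximum-likelihood logistic
regression (the antilog of the exposure coefficient) with Wald intervals
from the ML standard errors.  Candidate confounders beyond the core set
are screened by the change-in-estimate rule: a candidate is kept only if
adding it moves the adjusted exposure OR by more than 10%.

The exposure-response shape is examined by locally weighted scatterplot
smoothing (LOESS) of the case indicator on continuous cumulative RDD: the
smoothed proportion is clipped away from {0,1} and logit-transformed, and
a data-driven "high exposure" cut point is the smallest RDD after which
the smoothed logit rises monotonically for the rest of the range.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import logit
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import ParameterError, SmoothingError
from .exposure import LATENCIES, PercentileCuts

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # standard normal 97.5% point

CORE_COVARIATES = ["age", "vital_status", "family_history",
                   "personal_history", "age_first_birth",
                   "occupational_pce", "study_origin"]


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure x disease counts: a,b exposed cases/controls; c,d referent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ParameterError("cell counts must be non-negative")


@dataclass(frozen=True)
class ORResult:
    """Odds ratio with 95% CI; undefined (NaN) when a cell is zero."""

    oddsratio: float
    ci_low: float
    ci_high: float
    defined: bool
    n_cells: tuple = ()

    def rounded(self, ndigits: int = 1):
        if not self.defined:
            return (float("nan"),) * 3
        return tuple(round(v, ndigits)
                     for v in (self.oddsratio, self.ci_low, self.ci_high))


def crude_or(t: TwoByTwo) -> ORResult:
    """Crude OR = ad/bc with a Woolf 95% interval.

    A zero cell leaves the estimate undefined — no continuity correction —
    mirroring how sparse strata are reported as missing.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        return ORResult(float("nan"), float("nan"), float("nan"),
                        defined=False, n_cells=(a, b, c, d))
    oratio = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = (math.exp(math.log(oratio) - Z95 * se),
              math.exp(math.log(oratio) + Z95 * se))
    return ORResult(oratio, lo, hi, defined=True, n_cells=(a, b, c, d))


class LogisticFit:
    """Thin wrapper around a fitted ML logistic regression."""

    def __init__(self, result, exposure: str | None):
        self._result = result
        self.exposure = exposure
        self.params = result.params
        self.bse = result.bse

    def aor(self, term: str | None = None) -> ORResult:
        """Adjusted OR (antilog of the coefficient) with Wald 95% CI."""
        term = term or self.exposure
        beta, se = self.params[term], self.bse[term]
        return ORResult(math.exp(beta), math.exp(beta - Z95 * se),
                        math.exp(beta + Z95 * se), defined=True)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "se": self.bse,
                             "aor": np.exp(self.params),
                             "ci_low": np.exp(self.params - Z95 * self.bse),
                             "ci_high": np.exp(self.params + Z95 * self.bse)})


def fit_logistic(outcome, design: pd.DataFrame,
                 exposure: str | None = None) -> LogisticFit:
    """Maximum-likelihood logistic regression (IRLS/Newton).

    ``design`` holds the covariate columns (no constant; one is added).
    Raises :class:`ParameterError` on separation or a singular design,
    naming the offending structure where detectable.
    """
    y = np.asarray(outcome, dtype=float)
    X = sm.add_constant(pd.DataFrame(design).astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        degenerate = [c for c in X.columns if c != "const"
                      and np.ptp(X[c].to_numpy()) == 0]
        raise ParameterError(
            "singular design matrix"
            + (f"; constant column(s): {degenerate}" if degenerate else ""))
    if len(y) <= X.shape[1]:
        raise ParameterError("need more observations than parameters")
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as e:
        raise ParameterError(f"logistic fit failed: {e}") from e
    if not res.mle_retvals.get("converged", True):
        raise ParameterError("logistic fit did not converge "
                             "(possible separation)")
    return LogisticFit(res, exposure)


def confounder_screen(outcome, exposure_col: str, core: pd.DataFrame,
                      candidates: pd.DataFrame,
                      threshold: float = 0.10) -> tuple[list[str], pd.DataFrame]:
    """Change-in-estimate screen for candidate confounders.

    A candidate is kept iff adding it alone to the core model changes the
    adjusted exposure OR by more than ``threshold`` (relative).  Candidates
    that break convergence are flagged, logged and not kept.
    """
    base = fit_logistic(outcome, core, exposure=exposure_col).aor().oddsratio
    rows, kept = [], []
    for name in candidates.columns:
        try:
            with_c = fit_logistic(
                outcome, pd.concat([core, candidates[[name]]], axis=1),
                exposure=exposure_col).aor().oddsratio
            change = abs(with_c - base) / base
            keep = change > threshold
        except ParameterError as e:
            logger.warning("candidate %r broke the fit (%s); not kept", name, e)
            with_c, change, keep = float("nan"), float("nan"), False
        if keep:
            kept.append(name)
        rows.append({"candidate": name, "aor_core": base, "aor_with": with_c,
                     "rel_change": change, "kept": keep})
    return kept, pd.DataFrame(rows)


@dataclass
class SmoothCurve:
    """LOESS-smoothed logit of disease against continuous RDD."""

    span: float
    rdd: np.ndarray     # evaluation grid, sorted
    smoothed_logit: np.ndarray


def loess_logit(rdd, outcome, span: float = 0.2,
                grid_size: int = 200) -> SmoothCurve:
    """Local-linear smoothing of the 0/1 outcome on RDD, on the logit scale.

    The fitted proportions are clipped to [1e-4, 1-1e-4] before the logit
    transform so the curve stays finite.
    """
    x = np.asarray(rdd, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if not (0.05 <= span <= 1.0):
        raise ParameterError("span must lie in [0.05, 1]")
    if x.size < 50:
        raise SmoothingError("need at least 50 subjects to smooth")
    if span * x.size < 5:
        raise SmoothingError("span too small for local neighborhoods")
    grid = np.linspace(x.min(), x.max(), grid_size)
    fitted = lowess(y, x, frac=span, xvals=grid)
    fitted = np.clip(fitted, 1e-4, 1 - 1e-4)
    return SmoothCurve(span=span, rdd=grid, smoothed_logit=logit(fitted))


NO_CUTPOINT = None  # sentinel returned when no rising tail exists


def select_cutpoint(curve: SmoothCurve, rule=None, min_gap: float = 0.2):
    """Data-driven high-exposure cut point from a smoothed curve.

    Default rule — the smallest grid RDD after which the smoothed logit
    sits in its elevated regime and keeps rising:

    * A curve that is non-decreasing over the whole grid rises from the
      start, so the first grid point is returned; one that never rises
      (flat or decreasing) has no high-exposure regime and returns the
      sentinel ``None``.
    * Otherwise the transition is located by the CUSUM change-point
      statistic (the split maximizing the weighted mean-after minus
      mean-before), which estimates the regime boundary independently of
      the smoothing span, and is refined backward along the final
      non-decreasing stretch of the curve — but not below the halfway
      level of the rise, so sampling wiggles in the smoothed lower regime
      cannot drag the cut toward zero.  A split whose mean gap is below
      ``min_gap`` of the curve's range is treated as no rise.

    Pass ``rule`` (a callable on the curve) to substitute another
    selection rule.
    """
    if curve.rdd.size < 3:
        raise ParameterError("curve needs at least 3 grid points")
    if rule is not None:
        return rule(curve)
    z = curve.smoothed_logit
    n = z.size
    rng = float(np.ptp(z))
    if rng == 0.0:
        return NO_CUTPOINT
    d = np.diff(z)
    if np.all(d >= 0):
        return float(curve.rdd[0])
    if np.all(d <= 0):
        return NO_CUTPOINT
    cum = np.concatenate([[0.0], np.cumsum(z)])
    t = np.arange(1, n)
    gap = (cum[-1] - cum[t]) / (n - t) - cum[t] / t  # mean after - before
    cusum = np.sqrt(t * (n - t)) * gap  # downweights edge splits
    split = int(t[np.argmax(cusum)])
    if gap[split - 1] < min_gap * rng:
        return NO_CUTPOINT
    low = float(cum[split] / split)
    high = float((cum[-1] - cum[split]) / (n - split))
    floor = low + 0.5 * (high - low)
    start = split
    for i in range(split - 1, -1, -1):
        if d[i] < 0 or z[i] < floor:
            break
        start = i
    return float(curve.rdd[start])


def wilcoxon_signed_rank(paired_a, paired_b) -> tuple[float, float, bool]:
    """Two-sided Wilcoxon signed-rank test on paired vectors.

    Zero differences are dropped.  For n <= 25 the p-value is exact,
    computed from the tie-aware null distribution of the positive-rank sum;
    beyond that the tie-corrected normal approximation is used.  Returns
    (W+, p, flagged); ``flagged`` is True when every pair is identical, in
    which case p = 1 by convention.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0, True
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= 25:
        p = _exact_signed_rank_p(ranks, w_pos)
    else:
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = (counts ** 3 - counts).sum() / 48.0
        sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (w_pos - mu) / sigma
        p = 2 * stats.norm.sf(abs(z))
    return w_pos, min(p, 1.0), False


def _exact_signed_rank_p(ranks, w_pos: float) -> float:
    """Exact two-sided p for W+ by dynamic programming over sign flips.

    Ranks may be half-integers under ties; doubling makes them integral.
    """
    r2 = np.rint(2 * np.asarray(ranks)).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(2 * w_pos))
    p_low = dist[:w2 + 1].sum()
    p_high = dist[w2:].sum()
    return float(min(1.0, 2 * min(p_low, p_high)))


# ---------------------------------------------------------------------------
# Latency x category OR tables and method-comparison cross-tabulation

CATEGORY_ORDER = ["ever", "le_median", "gt_median", "gt_p75", "gt_p90"]


def _category_masks(cum: np.ndarray, ever: np.ndarray, cuts: PercentileCuts,
                    extra_cut: float | None):
    masks = {
        "ever": ever,
        "le_median": ever & (cum <= cuts.median),
        "gt_median": ever & (cum > cuts.median),
        "gt_p75": ever & (cum > cuts.p75),
        "gt_p90": ever & (cum > cuts.p90),
    }
    if extra_cut is not None:
        masks["gt_cut"] = ever & (cum > extra_cut)
    return masks


def run_latency_table(subjects: pd.DataFrame, metrics: pd.DataFrame,
                      cuts: dict[int, PercentileCuts],
                      latencies=LATENCIES,
                      covariates=CORE_COVARIATES,
                      extra_cut: float | None = None,
                      stratum: pd.Series | None = None) -> pd.DataFrame:
    """Crude and adjusted ORs per latency x exposure category.

    The referent is the never-exposed-over-the-whole-study-period group
    (not exposed at latency 0).  ``extra_cut`` adds a smoothing-cut-point
    category; ``stratum`` (boolean per subject, e.g. regular bottled-water
    use) restricts both exposed and referent groups to each stratum level
    in turn.  Cells with a zero count yield undefined (NaN) ORs.
    """
    known = set(metrics["latency"].unique())
    for L in latencies:
        if L not in known:
            raise ParameterError(f"metrics not computed for latency {L}")
    subs = subjects.set_index("subject_id")
    is_case = (subs["status"] == "case").to_numpy()
    m0 = metrics[metrics["latency"] == 0].set_index("subject_id")
    referent = ~m0.loc[subs.index, "ever"].to_numpy()

    strata = [("all", np.ones(len(subs), dtype=bool))]
    if stratum is not None:
        s = stratum.reindex(subs.index).astype(bool).to_numpy()
        strata = [("stratum=True", s), ("stratum=False", ~s)]

    cov = subs[list(covariates)].astype(float) if covariates else None
    rows = []
    for L in latencies:
        mL = metrics[metrics["latency"] == L].set_index("subject_id")
        cum = mL.loc[subs.index, "cumulative"].to_numpy()
        ever = mL.loc[subs.index, "ever"].to_numpy()
        masks = _category_masks(cum, ever, cuts[L], extra_cut)
        for sname, smask in strata:
            for cat, cmask in masks.items():
                exp_mask = cmask & smask
                ref_mask = referent & smask
                t = TwoByTwo(int((exp_mask & is_case).sum()),
                             int((exp_mask & ~is_case).sum()),
                             int((ref_mask & is_case).sum()),
                             int((ref_mask & ~is_case).sum()))
                cor = crude_or(t)
                aor = ORResult(*(float("nan"),) * 3, defined=False)
                if cov is not None and cor.defined:
                    sel = exp_mask | ref_mask
                    design = cov[sel].copy()
                    design.insert(0, "exposed", exp_mask[sel].astype(float))
                    try:
                        aor = fit_logistic(is_case[sel], design,
                                           exposure="exposed").aor()
                    except ParameterError as e:
                        logger.warning("adjusted OR unavailable (L=%s, %s): %s",
                                       L, cat, e)
                rows.append({
                    "latency": L, "stratum": sname, "category": cat,
                    "cases": t.a, "controls": t.b,
                    "ref_cases": t.c, "ref_controls": t.d,
                    "cor": cor.oddsratio, "cor_low": cor.ci_low,
                    "cor_high": cor.ci_high,
                    "aor": aor.oddsratio, "aor_low": aor.ci_low,
                    "aor_high": aor.ci_high,
                })
    return pd.DataFrame(rows)


def exposure_crosstab(categories_a, categories_b,
                      order=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tabulate two categorical exposure classifications.

    Accepts per-subject labels from two assessment methods (e.g. a manual
    and an automated reconstruction) and returns (counts, row-percentages),
    the row percentages rounded to 2 decimals.
    """
    a = pd.Series(list(categories_a), name="method_a")
    b = pd.Series(list(categories_b), name="method_b")
    counts = pd.crosstab(a, b)
    if order is not None:
        counts = counts.reindex(index=order, columns=order, fill_value=0)
    row_pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return counts, row_pct.round(2)
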