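"""Downstream assay statistics: MTT viability, deposition comparison,
ThT dose-trend, and Welch's t-test with significance stars.

All group comparisons use the two-tailed Welch (unequal-variance) t-test:

    t  = (mean_x - mean_y) / sqrt(s_x^2/n_x + s_y^2/n_y)
    df = (s_x^2/n_x + s_y^2/n_y)^2
         / [ (s_x^2/n_x)^2/(n_x - 1) + (s_y^2/n_y)^2/(n_y - 1) ]

with the two-sided p-value from the t distribution (computed through the
regularized incomplete beta function, via scipy).  Two star conventions are
in circulation for the third level; both are provided:

* ``STAR_THRESHOLDS_DEFAULT`` = (0.05, 0.01, 0.005)
* ``STAR_THRESHOLDS_ALT``     = (0.05, 0.01, 0.001)

MTT viability is reported relative to the vehicle-treated (no amyloid, no
extract) control group, which defines 100 %; the amyloid-only group is a
comparison group, not the baseline.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "STAR_THRESHOLDS_DEFAULT",
    "STAR_THRESHOLDS_ALT",
    "WelchResult",
    "ThTTrace",
    "ThTTrendResult",
    "star_label",
    "welch_t",
    "relative_viability",
    "deposition_compare",
    "tht_dose_trend",
    "traces_from_wide",
]

STAR_THRESHOLDS_DEFAULT = (0.05, 0.01, 0.005)
STAR_THRESHOLDS_ALT = (0.05, 0.01, 0.001)


@dataclass
class WelchResult:
    """Welch two-sample t-test outcome."""

    t_stat: float
    df: float
    p_two_sided: float
    stars: str
    thresholds: tuple[float, float, float] = STAR_THRESHOLDS_DEFAULT


@dataclass
class ThTTrace:
    """One ThT fluorescence time course at a given condition."""

    condition: str
    conc: float
    times: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.size == 0 or self.times.size != self.fluorescence.size:
            raise ValueError("times and fluorescence must be non-empty and equal length")
        if self.times[0] < 0 or self.times[-1] > 24:
            raise ValueError("times must lie within [0, 24] h")

    @property
    def endpoint_24h(self) -> float:
        """Fluorescence at the final measured time point."""
        return float(self.fluorescence[-1])


@dataclass
class ThTTrendResult:
    """Concentration-dependence of the ThT endpoint."""

    endpoints: pd.DataFrame        # conc, endpoint, relative_to_control
    agreement: float               # Spearman rho of endpoint vs concentration
    p_perm: float                  # exact permutation p (one-sided, decreasing)
    trend: str                     # "decreasing" | "increasing" | "no trend"


def star_label(p: float, thresholds: tuple[float, float, float] = STAR_THRESHOLDS_DEFAULT) -> str:
    """Significance stars: the most extreme threshold strictly exceeded wins."""
    if not 0.0 <= p <= 1.0 or not math.isfinite(p):
        raise ValueError(f"p must be within [0, 1], got {p}")
    t1, t2, t3 = thresholds
    if p < t3:
        return "***"
    if p < t2:
        return "**"
    if p < t1:
        return "*"
    return ""


def welch_t(x, y, thresholds: tuple[float, float, float] = STAR_THRESHOLDS_DEFAULT) -> WelchResult:
    """Two-tailed Welch t-test between two samples.

    Requires n >= 2 in each sample.  If both variances are zero the test is
    degenerate: p = 1 by convention when the means coincide, p = 0 when
    they differ.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError(f"each sample needs >= 2 values (got {nx} and {ny})")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return WelchResult(0.0, float(nx + ny - 2), 1.0, "", thresholds)
        t = math.inf if x.mean() > y.mean() else -math.inf
        return WelchResult(t, float(nx + ny - 2), 0.0, star_label(0.0, thresholds), thresholds)
    se2x, se2y = vx / nx, vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2x + se2y)
    df = (se2x + se2y) ** 2 / (se2x ** 2 / (nx - 1) + se2y ** 2 / (ny - 1))
    # two-sided tail probability of the t distribution (regularized
    # incomplete beta under the hood)
    p = float(2.0 * sps.t.sf(abs(t), df))
    return WelchResult(float(t), float(df), p, star_label(p, thresholds), thresholds)


def relative_viability(groups: dict[str, np.ndarray] | pd.DataFrame,
                       control_group: str) -> pd.Series:
    """Per-group mean absorbance as a percentage of the control-group mean.

    ``groups`` is either a mapping label -> absorbances or a long table
    with columns ``group`` and ``absorbance``.  Gain applied uniformly to
    all absorbances cancels.
    """
    if isinstance(groups, pd.DataFrame):
        groups = {str(g): sub["absorbance"].to_numpy(dtype=float)
                  for g, sub in groups.groupby("group", sort=False)}
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} not present")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in arrays.items():
        if v.size == 0:
            raise ValueError(f"group {g!r} is empty")
        if np.any(v < 0):
            raise ValueError(f"group {g!r} has negative absorbances")
    ctrl_mean = arrays[control_group].mean()
    if ctrl_mean <= 0:
        raise ValueError(f"control group mean must be > 0, got {ctrl_mean}")
    return pd.Series({g: 100.0 * v.mean() / ctrl_mean for g, v in arrays.items()},
                     name="relative_pct")


def deposition_compare(groups: dict[str, np.ndarray] | pd.DataFrame, reference_group: str,
                       thresholds: tuple[float, float, float] = STAR_THRESHOLDS_DEFAULT
                       ) -> pd.DataFrame:
    """Welch-test each treated group's deposition scores against the
    amyloid-only reference group.

    ``groups`` maps label -> replicate mean-of-means values (or a long
    table with columns ``group`` and ``value``).  Returns one row per
    non-reference group with t, df, p, stars and the effect direction.
    """
    if isinstance(groups, pd.DataFrame):
        groups = {str(g): sub["value"].to_numpy(dtype=float)
                  for g, sub in groups.groupby("group", sort=False)}
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not present")
    ref = np.asarray(groups[reference_group], dtype=float)
    rows = []
    for name in sorted(g for g in groups if g != reference_group):
        vals = np.asarray(groups[name], dtype=float)
        res = welch_t(vals, ref, thresholds)
        if res.p_two_sided < thresholds[0]:
            direction = "reduction" if vals.mean() < ref.mean() else "increase"
        else:
            direction = "none"
        rows.append(dict(group=name, reference=reference_group, t=res.t_stat, df=res.df,
                         p=res.p_two_sided, stars=res.stars, direction=direction,
                         mean=vals.mean(), reference_mean=ref.mean()))
    return pd.DataFrame(rows)


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    import warnings

    with warnings.catch_warnings():
        # constant endpoints are a legitimate "no trend" outcome, not an error
        warnings.simplefilter("ignore", sps.ConstantInputWarning)
        rho = sps.spearmanr(a, b).statistic
    return 0.0 if not np.isfinite(rho) else float(rho)


def tht_dose_trend(traces: list[ThTTrace], max_exact: int = 8) -> ThTTrendResult:
    """Concentration-dependence of the 24 h ThT endpoint.

    Endpoints at each inhibitor concentration are expressed relative to the
    amyloid-only trace (conc == 0); the trend statistic is the Spearman
    rank agreement between concentration and endpoint (-1 = perfectly
    decreasing).  For <= ``max_exact`` concentrations the one-sided
    p-value (toward decreasing) is computed by exact enumeration of all
    endpoint orderings.
    """
    if not traces:
        raise ValueError("no traces supplied")
    t0 = traces[0].times
    for tr in traces[1:]:
        if tr.times.size != t0.size or not np.allclose(tr.times, t0):
            raise ValueError(f"trace {tr.condition!r} has a mismatched time grid")
    control = [tr for tr in traces if tr.conc == 0]
    if not control:
        raise ValueError("an amyloid-only trace (conc == 0) is required")
    ref_endpoint = control[0].endpoint_24h
    dosed = sorted((tr for tr in traces if tr.conc > 0), key=lambda tr: tr.conc)
    if len(dosed) < 3:
        raise ValueError("need >= 3 positive concentrations for a trend")
    concs = np.array([tr.conc for tr in dosed])
    ends = np.array([tr.endpoint_24h for tr in dosed])
    rel = ends / ref_endpoint if ref_endpoint != 0 else np.full_like(ends, np.nan)
    rho = _spearman(concs, ends)

    if len(dosed) <= max_exact:
        n_le = sum(1 for perm in itertools.permutations(ends)
                   if _spearman(concs, np.array(perm)) <= rho + 1e-12)
        p = n_le / math.factorial(len(dosed))
    else:  # asymptotic fallback for long ladders
        p = float(sps.spearmanr(concs, ends, alternative="less").pvalue)

    if rho < 0 and p < 0.5:
        trend = "decreasing"
    elif rho > 0:
        trend = "increasing"
    else:
        trend = "no trend"
    endpoints = pd.DataFrame({"conc": concs, "endpoint": ends, "relative_to_control": rel})
    return ThTTrendResult(endpoints, rho, p, trend)


def traces_from_wide(df: pd.DataFrame, time_col: str = "time_h") -> list[ThTTrace]:
    """Build traces from a wide ThT table (``time_h`` + ``conc_<x>`` columns)."""
    traces = []
    for col in df.columns:
        if col == time_col:
            continue
        if not col.startswith("conc_"):
            raise ValueError(f"unrecognized ThT column {col!r}; expected conc_<x>")
        conc = float(col.removeprefix("conc_"))
        traces.append(ThTTrace(condition=col, conc=conc,
                               times=df[time_col].to_numpy(),
                               fluorescence=df[col].to_numpy()))
    return traces
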