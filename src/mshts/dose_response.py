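"""Dose-response normalization, asymmetric-logistic fitting and EC50.

The screening readout for a well is the SD aggregation score; it is
expressed as a percentage of the mean score of the aggregation-only
(``abeta_control``) wells.  Inhibition curves of normalized score versus
inhibitor concentration x are modeled with the asymmetric five-parameter
logistic (5PL)

    y(x) = d + (a - d) / (1 + (x/c)^b)^g

with upper plateau ``a`` (% of control), lower plateau ``d``, location
``c`` (ug/mL), slope ``b`` > 0 and asymmetry ``g`` > 0; for g = 1 this is
the familiar symmetric 4PL with midpoint c.  The half-maximal effective
concentration is defined relative to the fitted plateaus,

    EC50 = c * (2^(1/g) - 1)^(1/b),

the unique x where y = (a + d)/2.  Samples whose normalized score never
drops below 50 % of control at the highest tested concentration are marked
ND (not determined) and are not fitted.

Two fitting modes exist.  ``per_replicate`` (default) fits each replicate
curve separately and reports EC50 as mean ± SD over replicates, matching
how screening results are usually reported; ``global`` pools all
replicates into a single fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "FivePLFit",
    "EC50Result",
    "DoseResponseSeries",
    "DoseResponseModel",
    "DoseResponseResults",
    "NormalizationError",
    "five_pl",
    "ec50_from_params",
    "ec50_to_c",
    "normalize",
    "nd_rule",
    "fit_series",
]

#: ND threshold: normalized SD not less than this (in % of control) at the
#: top tested concentration means no EC50 can be determined.
ND_THRESHOLD_PCT = 50.0


class NormalizationError(ValueError):
    """Control wells absent or their mean score unusable."""


@dataclass
class FivePLFit:
    """Fitted 5PL parameters for one curve (one replicate or pooled)."""

    a: float
    d: float
    c: float
    b: float
    g: float
    converged: bool
    rss: float
    n_points: int = 0
    replicate: int | None = None
    message: str = ""

    def predict(self, x) -> np.ndarray:
        return five_pl(x, self.a, self.d, self.c, self.b, self.g)

    def ec50(self) -> float:
        """Relative EC50: halfway between the fitted plateaus (closed form)."""
        return ec50_from_params(self.a, self.d, self.c, self.b, self.g)

    def ec50_absolute(self, level_pct: float = 50.0) -> float:
        """Concentration where the fitted curve crosses ``level_pct`` %
        of control (NaN when the curve never reaches it)."""
        if not (self.d < level_pct < self.a):
            return float("nan")
        z = ((self.a - self.d) / (level_pct - self.d)) ** (1.0 / self.g) - 1.0
        return self.c * z ** (1.0 / self.b)


@dataclass
class EC50Result:
    """EC50 summary for one sample: mean ± SD over replicate fits."""

    sample_id: str
    ec50_mean: float
    ec50_sd: float
    n_replicates: int
    nd_flag: bool

    def __post_init__(self) -> None:
        if self.nd_flag:
            # ND results carry no numeric EC50
            self.ec50_mean = float("nan")
            self.ec50_sd = float("nan")


@dataclass
class DoseResponseSeries:
    """Normalized aggregation scores of one sample versus concentration.

    ``points`` has columns ``conc_ug_ml``, ``sd_norm`` (% of control) and
    ``replicate``.
    """

    sample_id: str
    points: pd.DataFrame
    control_mean_sd: float = float("nan")

    def __post_init__(self) -> None:
        needed = {"conc_ug_ml", "sd_norm", "replicate"}
        missing = needed - set(self.points.columns)
        if missing:
            raise ValueError(f"series points missing columns {sorted(missing)}")
        if len(self.points) == 0:
            raise ValueError("series has no points")
        if (self.points["conc_ug_ml"] < 0).any():
            raise ValueError("concentrations must be >= 0")


# ---------------------------------------------------------------------------
# the 5PL curve and its closed forms

def five_pl(x, a: float, d: float, c: float, b: float, g: float):
    """Evaluate the asymmetric five-parameter logistic at concentration x."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("concentrations must be finite and >= 0")
    if c <= 0 or b <= 0 or g <= 0:
        raise ValueError("c, b, g must all be > 0")
    with np.errstate(over="ignore"):  # (x/c)^b -> inf far above c is benign: y -> d
        y = d + (a - d) / (1.0 + (x / c) ** b) ** g
    return float(y) if y.ndim == 0 else y


def ec50_from_params(a: float | FivePLFit, d: float | None = None, c: float | None = None,
                     b: float | None = None, g: float | None = None) -> float:
    """Closed-form EC50: the x where the 5PL is halfway between its plateaus.

    EC50 = c * (2^(1/g) - 1)^(1/b); reduces to c for g = 1.
    """
    if isinstance(a, FivePLFit):
        fit = a
        a, d, c, b, g = fit.a, fit.d, fit.c, fit.b, fit.g
    if c <= 0 or b <= 0 or g <= 0:
        raise ValueError("c, b, g must all be > 0")
    if a == d:
        raise ValueError("EC50 undefined when the plateaus coincide (a == d)")
    return c * (2.0 ** (1.0 / g) - 1.0) ** (1.0 / b)


def ec50_to_c(ec50: float, b: float, g: float) -> float:
    """Inverse of :func:`ec50_from_params`: the c giving a desired EC50."""
    if ec50 <= 0 or b <= 0 or g <= 0:
        raise ValueError("ec50, b, g must all be > 0")
    return ec50 / (2.0 ** (1.0 / g) - 1.0) ** (1.0 / b)


# ---------------------------------------------------------------------------
# normalization and the ND rule

def normalize(scores: pd.DataFrame) -> dict[str, DoseResponseSeries]:
    """Express raw SD scores as % of the mean aggregation-control score.

    ``scores`` is the table produced by the imaging stage (columns
    ``sample_id, conc_ug_ml, replicate, role, sd_raw``).  Control wells map
    to 100 % on average; gain applied uniformly to the raw scores cancels.
    """
    ctrl = scores.loc[(scores["role"] == "abeta_control") & scores["sd_raw"].notna(), "sd_raw"]
    if len(ctrl) == 0:
        raise NormalizationError("no abeta_control wells with a valid score")
    control_mean = float(ctrl.mean())
    if not np.isfinite(control_mean) or control_mean <= 0:
        raise NormalizationError(f"control mean SD is unusable: {control_mean}")
    out: dict[str, DoseResponseSeries] = {}
    tests = scores[(scores["role"] == "test") & scores["sd_raw"].notna()]
    for sample_id, grp in tests.groupby("sample_id", sort=True):
        points = pd.DataFrame({
            "conc_ug_ml": grp["conc_ug_ml"].to_numpy(dtype=float),
            "sd_norm": 100.0 * grp["sd_raw"].to_numpy(dtype=float) / control_mean,
            "replicate": grp["replicate"].to_numpy(dtype=int),
        })
        out[str(sample_id)] = DoseResponseSeries(str(sample_id), points, control_mean)
    return out


def nd_rule(series: DoseResponseSeries, threshold_pct: float = ND_THRESHOLD_PCT) -> bool:
    """True (ND) when the mean normalized score at the top tested
    concentration is **not less than** the threshold (inclusive at 50 %)."""
    pts = series.points
    top = pts["conc_ug_ml"].max()
    top_mean = float(pts.loc[pts["conc_ug_ml"] == top, "sd_norm"].mean())
    return bool(top_mean >= threshold_pct)


# ---------------------------------------------------------------------------
# fitting engine

#: multistart factors applied to the (b, g) initialization, in order
_RESTART_FACTORS = [(1.0, 1.0), (0.5, 1.0), (2.0, 1.0), (1.0, 0.5), (1.0, 2.0)]


def _profile_starts(x: np.ndarray, y: np.ndarray, fix_g: float | None,
                    fix_b: float | None,
                    n_starts: int) -> list[tuple[float, float, float, float, float]]:
    """Candidate (a, d, c, b, g) starts from a coarse (c, b, g) grid.

    For fixed shape parameters the 5PL is linear in the plateaus (a, d),
    so each grid node costs one tiny linear least-squares solve; the best
    nodes seed the nonlinear refinement.  This keeps the fit out of the
    c-g trade-off valleys that trap single-start optimizers.
    """
    c_grid = np.geomspace(0.25 * x.min(), 4.0 * x.max(), 10)
    b_grid = (fix_b,) if fix_b is not None else (0.5, 1.0, 2.0, 4.0)
    g_grid = (fix_g,) if fix_g is not None else (0.25, 1.0, 4.0)
    scored = []
    for c in c_grid:
        xc = x / c
        for b in b_grid:
            base = 1.0 + xc ** b
            for g in g_grid:
                u = base ** -g
                # y ~ d + (a - d) u  ==  d (1 - u) + a u
                design = np.column_stack([u, 1.0 - u])
                coef, *_ = np.linalg.lstsq(design, y, rcond=None)
                a, d = float(coef[0]), float(coef[1])
                rss = float(np.sum((design @ coef - y) ** 2))
                scored.append((rss, a, d, float(c), float(b), float(g)))
    scored.sort(key=lambda s: s[0])
    return [s[1:] for s in scored[:n_starts]]


def _fit_curve(x: np.ndarray, y: np.ndarray, restarts: int = 5,
               fix_g: float | None = None, fix_b: float | None = None,
               replicate: int | None = None,
               a_bounds: tuple[float, float] | None = (90.0, 110.0),
               d_bounds: tuple[float, float] = (0.0, 70.0)) -> FivePLFit:
    """Least-squares 5PL fit of one curve (points at x > 0 only).

    The response is % of the aggregation-only control, so the upper
    plateau is anchored by the normalization itself: ``a_bounds`` defaults
    to (90, 110) % of control, the usual "constrain Top" convention for
    normalized dose-response data (pass ``None`` for data-driven bounds).
    Without this anchor the plateau - and hence the EC50 - is
    unidentifiable for potent samples whose whole tested range lies on
    the descending limb.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pos = x > 0
    x, y = x[pos], y[pos]
    if len(np.unique(x)) < 3:
        raise ValueError("at least 3 distinct positive concentrations required")
    n = len(x)
    if fix_g is None and n < 5:
        fix_g = 1.0  # too few points for 5 free parameters
    ymax, ymin = float(y.max()), float(y.min())
    if ymax - ymin < 1e-9 * max(1.0, abs(ymax)):
        return FivePLFit(a=ymax, d=ymin, c=float(np.sqrt(x.min() * x.max())), b=1.0, g=1.0,
                         converged=False, rss=float("nan"), n_points=n, replicate=replicate,
                         message="degenerate series: response is constant")

    # bounds: upper plateau anchored by normalization (or data-driven when
    # a_bounds is None); c within 0.01x-100x the tested range; b, g within
    # (0.01, 50]
    if a_bounds is None:
        lo_a, hi_a = max(0.0, 0.5 * ymax), 2.0 * ymax
    else:
        lo_a, hi_a = a_bounds
        hi_a = max(hi_a, 1.05 * ymax)  # never exclude the observed maximum
    lo_d, hi_d = d_bounds
    hi_d = min(hi_d, ymax)
    lo_c, hi_c = 0.01 * x.min(), 100.0 * x.max()
    lo_bg, hi_bg = 0.01, 50.0
    c0 = float(np.sqrt(x.min() * x.max()))  # geometric mid-concentration
    logx = np.log(x)

    with_b = fix_b is None
    with_g = fix_g is None
    lo = [lo_a, lo_d, np.log10(lo_c)]
    hi = [hi_a, hi_d, np.log10(hi_c)]
    if with_b:
        lo.append(np.log10(lo_bg))
        hi.append(np.log10(hi_bg))
    if with_g:
        lo.append(np.log10(lo_bg))
        hi.append(np.log10(hi_bg))
    lo, hi = np.array(lo), np.array(hi)
    ln10 = math.log(10.0)

    def unpack(theta):
        a, d, logc = theta[:3]
        i = 3
        if with_b:
            b = 10.0 ** theta[i]
            i += 1
        else:
            b = fix_b
        g = 10.0 ** theta[i] if with_g else fix_g
        return a, d, 10.0 ** logc, b, g

    def residuals(theta):
        a, d, c, b, g = unpack(theta)
        yhat = d + (a - d) / (1.0 + np.exp(b * (logx - math.log(c)))) ** g
        return yhat - y

    def pack(a0, d0, cc, bb, gg) -> list[float]:
        theta0 = [np.clip(a0, lo_a, hi_a), np.clip(d0, lo_d, hi_d),
                  np.clip(np.log10(cc), lo[2], hi[2])]
        i = 3
        if with_b:
            theta0.append(float(np.clip(np.log10(bb), lo[i], hi[i])))
            i += 1
        if with_g:
            theta0.append(float(np.clip(np.log10(gg), lo[i], hi[i])))
        return theta0

    starts: list[list[float]] = []
    for fb, fg in _RESTART_FACTORS[:max(1, restarts)]:
        starts.append(pack(ymax, ymin, c0, (fix_b or 1.0) * fb, (fix_g or 1.0) * fg))
    for a0, d0, cc, bb, gg in _profile_starts(x, y, fix_g, fix_b,
                                              n_starts=max(1, restarts)):
        starts.append(pack(a0, d0, cc, bb, gg))

    candidates: list[FivePLFit] = []
    for theta0 in starts:
        try:
            res = least_squares(residuals, theta0, bounds=(lo, hi),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=5000)
        except Exception as exc:  # pragma: no cover - optimizer pathologies
            candidates.append(FivePLFit(ymax, ymin, c0, fix_b or 1.0, fix_g or 1.0, False,
                                        float("inf"), n, replicate, str(exc)))
            continue
        a, d, c, b, g = unpack(res.x)
        fit = FivePLFit(a=float(a), d=float(d), c=float(c), b=float(b), g=float(g),
                        converged=bool(res.success and np.isfinite(res.cost)),
                        rss=float(2.0 * res.cost), n_points=n, replicate=replicate,
                        message="" if res.success else res.message)
        candidates.append(fit)

    good = [f for f in candidates if f.converged] or candidates
    # best RSS wins; near-ties broken by smaller asymmetry g
    best_rss = min(f.rss for f in good if np.isfinite(f.rss))
    tied = [f for f in good if np.isfinite(f.rss) and f.rss <= best_rss * (1 + 1e-9) + 1e-12]
    return min(tied, key=lambda f: f.g)


def fit_series(series: DoseResponseSeries, mode: str = "per_replicate",
               nd_threshold_pct: float = ND_THRESHOLD_PCT, apply_nd: bool = True,
               restarts: int = 5, fix_g: float | None = None,
               share_shape: bool = True, ec50_definition: str = "absolute50"
               ) -> tuple[list[FivePLFit], EC50Result]:
    """Fit a sample's inhibition curve(s) and summarize EC50.

    ``global`` pools every point into one fit (its EC50 SD is NaN since a
    single pooled fit yields one estimate).  ``per_replicate`` reports
    EC50 as mean ± SD over replicate curves; by default the slope and
    asymmetry (b, g) are shared across replicates - they are estimated
    once from the pooled points, and each replicate then refits only the
    plateaus and location (a, d, c).  Sharing shape parameters across
    replicate curves stabilizes the five-parameter family, which is
    under-determined by a single short dilution series; pass
    ``share_shape=False`` for fully independent replicate fits.

    ``ec50_definition`` selects how EC50 is read off a fitted curve:
    ``"absolute50"`` (default) is the concentration where the curve
    crosses 50 % of control - the natural partner of the 50 % ND rule on
    control-normalized data, and insensitive to plateau extrapolation on
    short dilution series; ``"relative"`` is the classical halfway point
    between the fitted plateaus (:func:`ec50_from_params`).
    ND series (see :func:`nd_rule`) skip fitting entirely.
    """
    if mode not in ("per_replicate", "global"):
        raise ValueError(f"unknown fit mode {mode!r}")
    if ec50_definition not in ("absolute50", "relative"):
        raise ValueError(f"unknown ec50_definition {ec50_definition!r}")

    def read_ec50(fit: FivePLFit) -> float:
        if ec50_definition == "absolute50":
            return fit.ec50_absolute(50.0)
        return fit.ec50()

    pts = series.points
    if len(np.unique(pts.loc[pts["conc_ug_ml"] > 0, "conc_ug_ml"])) < 3:
        raise ValueError("at least 3 distinct positive concentrations required")
    if apply_nd and nd_rule(series, nd_threshold_pct):
        return [], EC50Result(series.sample_id, float("nan"), float("nan"), 0, True)

    fits: list[FivePLFit] = []
    if mode == "global":
        fit = _fit_curve(pts["conc_ug_ml"].to_numpy(), pts["sd_norm"].to_numpy(),
                         restarts=restarts, fix_g=fix_g)
        fits.append(fit)
        ec50 = read_ec50(fit) if fit.converged else float("nan")
        n_reps = int(pts["replicate"].nunique())
        return fits, EC50Result(series.sample_id, float(ec50), float("nan"), n_reps, False)

    fix_b = None
    if share_shape and pts["replicate"].nunique() > 1:
        pooled = _fit_curve(pts["conc_ug_ml"].to_numpy(), pts["sd_norm"].to_numpy(),
                            restarts=restarts, fix_g=fix_g)
        if pooled.converged:
            fix_b, fix_g = pooled.b, pooled.g

    ec50s = []
    for rep, grp in pts.groupby("replicate", sort=True):
        fit = _fit_curve(grp["conc_ug_ml"].to_numpy(), grp["sd_norm"].to_numpy(),
                         restarts=restarts, fix_g=fix_g, fix_b=fix_b, replicate=int(rep))
        fits.append(fit)
        if fit.converged:
            try:
                value = read_ec50(fit)
                if np.isfinite(value):
                    ec50s.append(value)
            except ValueError:
                pass
    if ec50s:
        mean = float(np.mean(ec50s))
        sd = float(np.std(ec50s, ddof=1)) if len(ec50s) > 1 else float("nan")
    else:
        mean, sd = float("nan"), float("nan")
    return fits, EC50Result(series.sample_id, mean, sd, len(ec50s), False)


# ---------------------------------------------------------------------------
# model / results objects

class DoseResponseModel:
    """Asymmetric-logistic inhibition-curve model for one sample.

    Built from a normalized dose-response series; ``fit()`` returns a
    :class:`DoseResponseResults` carrying the fitted curves, the EC50
    summary and diagnostics.
    """

    def __init__(self, series: DoseResponseSeries):
        self.series = series

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, sample_id: str,
                       conc_col: str = "conc_ug_ml", response_col: str = "sd_norm",
                       replicate_col: str = "replicate") -> "DoseResponseModel":
        points = pd.DataFrame({
            "conc_ug_ml": df[conc_col].to_numpy(dtype=float),
            "sd_norm": df[response_col].to_numpy(dtype=float),
            "replicate": (df[replicate_col].to_numpy(dtype=int)
                          if replicate_col in df.columns else np.ones(len(df), dtype=int)),
        })
        return cls(DoseResponseSeries(sample_id, points))

    @classmethod
    def from_scores(cls, scores: pd.DataFrame, sample_id: str) -> "DoseResponseModel":
        """Build from a raw score table (normalizes against its controls)."""
        series = normalize(scores)
        if sample_id not in series:
            raise KeyError(f"sample {sample_id!r} not found among test wells")
        return cls(series[sample_id])

    def fit(self, mode: str = "per_replicate", **kwargs) -> "DoseResponseResults":
        fits, ec50 = fit_series(self.series, mode=mode, **kwargs)
        return DoseResponseResults(self, fits, ec50, mode)


class DoseResponseResults:
    """Fit results: per-curve 5PL parameters, EC50 mean ± SD, ND flag."""

    def __init__(self, model: DoseResponseModel, fits: list[FivePLFit],
                 ec50: EC50Result, mode: str):
        self.model = model
        self.fits = fits
        self.ec50 = ec50
        self.mode = mode

    @property
    def nd_flag(self) -> bool:
        return self.ec50.nd_flag

    @property
    def ec50_mean(self) -> float:
        return self.ec50.ec50_mean

    @property
    def ec50_sd(self) -> float:
        return self.ec50.ec50_sd

    def best_fit(self) -> FivePLFit | None:
        good = [f for f in self.fits if f.converged and np.isfinite(f.rss)]
        return min(good, key=lambda f: f.rss) if good else None

    def predict(self, x) -> np.ndarray:
        fit = self.best_fit()
        if fit is None:
            raise ValueError("no converged fit available for prediction")
        return fit.predict(x)

    def summary(self) -> str:
        s = self.model.series
        lines = [
            f"Dose-response fit: sample {s.sample_id}",
            f"  mode           : {self.mode}",
            f"  n points       : {len(s.points)}"
            f" ({s.points['replicate'].nunique()} replicates)",
            f"  ND flag        : {self.nd_flag}",
        ]
        if self.nd_flag:
            lines.append("  EC50           : ND (top-concentration response >= 50% of control)")
            return "\n".join(lines)
        lines.append(f"  EC50 (ug/mL)   : {self.ec50_mean:.3g}"
                     + ("" if not np.isfinite(self.ec50_sd) else f" +/- {self.ec50_sd:.3g}")
                     + f" (n = {self.ec50.n_replicates})")
        lines.append("  curve fits     :")
        for f in self.fits:
            tag = f"rep {f.replicate}" if f.replicate is not None else "pooled"
            if f.converged:
                lines.append(f"    {tag}: a={f.a:.4g} d={f.d:.4g} c={f.c:.4g} "
                             f"b={f.b:.4g} g={f.g:.4g} rss={f.rss:.4g}")
            else:
                lines.append(f"    {tag}: NOT CONVERGED ({f.message})")
        return "\n".join(lines)

    def fits_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "sample_id": self.model.series.sample_id, "replicate": f.replicate,
            "a": f.a, "d": f.d, "c": f.c, "b": f.b, "g": f.g,
            "rss": f.rss, "converged": f.converged,
        } for f in self.fits])

    def plot(self, ax=None):
        """Scatter the normalized points with the best-fit curve overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pts = self.model.series.points
        ax.semilogx(pts["conc_ug_ml"], pts["sd_norm"], "o", alpha=0.6)
        fit = self.best_fit()
        if fit is not None:
            pos = pts.loc[pts["conc_ug_ml"] > 0, "conc_ug_ml"]
            grid = np.geomspace(pos.min(), pos.max(), 200)
            ax.semilogx(grid, fit.predict(grid), "-")
        ax.set_xlabel("concentration (ug/mL)")
        ax.set_ylabel("SD (% of control)")
        ax.set_title(self.model.series.sample_id)
        return ax
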