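"""Patlak graphical analysis of irreversibly trapped PET tracers.

For a tracer that enters an effectively irreversible tissue compartment
(FDG over a 60-min scan, acetoacetate over a 10-min scan), the ratio of
tissue activity to plasma activity becomes linear in "normalized time"

    theta(t) = int_0^t Cp(tau) dtau / Cp(t)

once the exchangeable compartments have equilibrated.  The slope of the
late linear segment is the net influx rate constant K (min^-1) — the
brain's capacity to extract the tracer from plasma — and the intercept is
the initial distribution volume.  K converts to a cerebral metabolic rate
(umol/100 g/min) through the plasma substrate concentration and the
lumped constant:

    CMR = 100 * K * Cp_met / (LC * rho)

with LC = 0.8 for the glucose tracer and 1.0 for acetoacetate, and tissue
density rho defaulting to 1 g/mL.

The model/results pair follows the statsmodels convention:
``PatlakModel(tac, ipf, t_star=10).fit()`` returns a :class:`PatlakResults`
carrying the estimates, their standard errors and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .schedules import FrameSchedule

__all__ = [
    "PlasmaInputFunction",
    "TimeActivityCurve",
    "PatlakModel",
    "PatlakResults",
    "PatlakFitError",
    "MetabolicRate",
    "patlak_fit",
    "integrate_input",
    "normalized_time",
    "cmr_from_k",
    "fit_regional_k",
]

GLUCOSE_TRACER = "glucose_tracer"
ACAC_TRACER = "acac_tracer"


class PatlakFitError(ValueError):
    """Raised when a Patlak fit is not identifiable (too few usable
    points, or no spread in normalized time)."""


@dataclass
class PlasmaInputFunction:
    """Sampled plasma tracer activity ("input function").

    Parameters
    ----------
    sample_times : array of float
        Sample times in minutes; strictly increasing, starting at 0.
    sample_values : array of float
        Plasma tracer activity concentration (kBq/mL); non-negative.
    cp_met : float, optional
        Plasma concentration of the cold metabolite (umol/mL ≡ mM for
        glucose/acetoacetate) used when converting K to a metabolic
        rate.  Distinct from the tracer activity curve.
    """

    sample_times: np.ndarray
    sample_values: np.ndarray
    cp_met: float | None = None

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.sample_values = np.asarray(self.sample_values, dtype=float)
        if self.sample_times.ndim != 1 or self.sample_times.shape != self.sample_values.shape:
            raise ValueError("sample_times and sample_values must be matching 1-D arrays")
        if self.sample_times[0] != 0.0:
            raise ValueError("input function samples must start at t=0")
        if np.any(np.diff(self.sample_times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(~np.isfinite(self.sample_values)) or np.any(self.sample_values < 0):
            raise ValueError("plasma activity must be finite and non-negative")
        # cumulative trapezoidal integral cached for interpolation
        self._cumint = cumulative_trapezoid(self.sample_values, self.sample_times, initial=0.0)

    @property
    def end_time(self) -> float:
        return float(self.sample_times[-1])

    def __call__(self, t) -> np.ndarray:
        """Linearly interpolated plasma activity at time(s) ``t`` (min)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or np.any(t > self.end_time):
            raise ValueError("time outside sampled support; no extrapolation")
        return np.interp(t, self.sample_times, self.sample_values)

    def integral(self, t) -> np.ndarray:
        """Trapezoidal integral of the interpolated curve from 0 to ``t``."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or np.any(t > self.end_time):
            raise ValueError("time outside sampled support; no extrapolation")
        # cumint is exact at sample knots; the partial segment beyond the last
        # knot is the trapezoid of the linearly interpolated curve, so the
        # result is exact for the piecewise-linear integrand.
        idx = np.searchsorted(self.sample_times, t, side="right") - 1
        idx = np.clip(idx, 0, len(self.sample_times) - 2)
        t0 = self.sample_times[idx]
        v0 = self.sample_values[idx]
        vt = np.interp(t, self.sample_times, self.sample_values)
        partial = 0.5 * (v0 + vt) * (t - t0)
        exact = self._cumint[idx] + partial
        return exact if exact.ndim else float(exact)

    def normalized_time(self, t) -> np.ndarray:
        """theta(t) = integral(t) / Cp(t); NaN where Cp(t) <= 0."""
        cp = np.asarray(self(t), dtype=float)
        integ = np.asarray(self.integral(t), dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            theta = np.where(cp > 0, integ / np.where(cp > 0, cp, 1.0), np.nan)
        # at t=0 both integral and Cp(0+) limit give theta -> 0
        theta = np.where(np.asarray(t, dtype=float) == 0.0, 0.0, theta)
        return theta if theta.ndim else float(theta)


def integrate_input(ipf: PlasmaInputFunction, t) -> float | np.ndarray:
    """Integral of the input curve from injection to ``t`` (kBq·min/mL)."""
    return ipf.integral(t)


def normalized_time(ipf: PlasmaInputFunction, t) -> float | np.ndarray:
    """Normalized time theta(t) (min); NaN where plasma activity is <= 0."""
    return ipf.normalized_time(t)


@dataclass
class TimeActivityCurve:
    """Frame-averaged tissue radioactivity for one tracer.

    ``values[i]`` is the mean activity concentration (kBq/mL) over
    ``schedule.frames[i]``.
    """

    schedule: FrameSchedule
    values: np.ndarray
    tracer_label: str = GLUCOSE_TRACER

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.schedule.n_frames,):
            raise ValueError("one value per frame required")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("TAC values must be finite")


class PatlakModel:
    """Patlak graphical model for one tissue curve and one input function.

    Parameters
    ----------
    tac : TimeActivityCurve
    ipf : PlasmaInputFunction
    t_star : float
        Start of the assumed-linear phase (min); frames whose midpoint is
        earlier are excluded.  Conventional defaults: 10 min for the
        60-min FDG protocol, 3 min for the 10-min acetoacetate protocol.
    weighting : {"uniform", "duration"}
        Least-squares weights; "duration" weights each frame by its
        length, down-weighting noisy short early frames.
    """

    def __init__(
        self,
        tac: TimeActivityCurve,
        ipf: PlasmaInputFunction,
        t_star: float = 10.0,
        weighting: str = "uniform",
    ) -> None:
        if weighting not in ("uniform", "duration"):
            raise ValueError("weighting must be 'uniform' or 'duration'")
        if t_star < 0:
            raise ValueError("t_star must be non-negative")
        self.tac = tac
        self.ipf = ipf
        self.t_star = float(t_star)
        self.weighting = weighting

    def _points(self) -> pd.DataFrame:
        mids = self.tac.schedule.midpoints
        cp = self.ipf(mids)
        theta = np.asarray(self.ipf.normalized_time(mids), dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(cp > 0, self.tac.values / np.where(cp > 0, cp, 1.0), np.nan)
        return pd.DataFrame(
            {
                "frame_mid": mids,
                "theta": theta,
                "ratio": ratio,
                "duration": self.tac.schedule.durations,
                "retained": (mids >= self.t_star) & np.isfinite(theta) & np.isfinite(ratio),
            }
        )

    def fit(self) -> "PatlakResults":
        pts = self._points()
        use = pts[pts["retained"]]
        if len(use) < 3:
            raise PatlakFitError(
                f"only {len(use)} usable frames after t*={self.t_star:g} min; need >= 3"
            )
        x = use["theta"].to_numpy()
        y = use["ratio"].to_numpy()
        w = use["duration"].to_numpy() if self.weighting == "duration" else np.ones_like(x)
        if np.ptp(x) <= 0:
            raise PatlakFitError("no spread in normalized time; slope unidentifiable")

        sw = w.sum()
        xbar = (w * x).sum() / sw
        ybar = (w * y).sum() / sw
        sxx = (w * (x - xbar) ** 2).sum()
        sxy = (w * (x - xbar) * (y - ybar)).sum()
        slope = sxy / sxx
        intercept = ybar - slope * xbar
        resid = y - (intercept + slope * x)
        syy = (w * (y - ybar) ** 2).sum()
        ssr = (w * resid**2).sum()
        r2 = 1.0 - ssr / syy if syy > 0 else 1.0
        n = len(x)
        dof = n - 2
        sigma2 = ssr / dof if dof > 0 else np.nan
        slope_se = float(np.sqrt(sigma2 / sxx)) if dof > 0 else np.nan
        return PatlakResults(
            K=float(slope),
            intercept=float(intercept),
            K_se=slope_se,
            r_squared=float(np.clip(r2, 0.0, 1.0)),
            t_star=self.t_star,
            n_points=n,
            points=pts,
            tracer_label=self.tac.tracer_label,
            model=self,
        )


@dataclass
class PatlakResults:
    """Estimated Patlak line for one tissue curve.

    Attributes
    ----------
    K : float
        Slope of the Patlak line — the net influx rate constant (min^-1).
        Negative estimates are retained and merely flagged downstream so
        that group statistics stay unbiased.
    intercept : float
        Initial distribution volume (unitless).
    K_se : float
        Standard error of the slope under i.i.d. residuals.
    r_squared : float
        Weighted coefficient of determination of the retained points.
    """

    K: float
    intercept: float
    K_se: float
    r_squared: float
    t_star: float
    n_points: int
    points: pd.DataFrame = field(repr=False)
    tracer_label: str = GLUCOSE_TRACER
    model: PatlakModel | None = field(default=None, repr=False)

    def to_cmr(self, cp_met: float | None = None, lc: float = 0.8, density: float = 1.0) -> "MetabolicRate":
        """Convert K to a cerebral metabolic rate (umol/100 g/min)."""
        if cp_met is None:
            cp_met = self.model.ipf.cp_met if self.model is not None else None
        if cp_met is None:
            raise ValueError("plasma metabolite concentration (cp_met) required")
        return cmr_from_k(self.K, cp_met, lc=lc, density=density)

    def summary(self) -> str:
        lines = [
            "Patlak graphical analysis",
            "=" * 41,
            f"tracer:          {self.tracer_label}",
            f"K (slope):       {self.K:.6f} min^-1  (SE {self.K_se:.6f})",
            f"intercept (V0):  {self.intercept:.4f}",
            f"R-squared:       {self.r_squared:.4f}",
            f"t*:              {self.t_star:g} min",
            f"n points:        {self.n_points}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Patlak plot: tissue/plasma ratio vs normalized time with the
        fitted line over the retained segment."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pts = self.points
        kept = pts[pts["retained"]]
        drop = pts[~pts["retained"]]
        ax.plot(drop["theta"], drop["ratio"], "o", mfc="none", color="grey", label="excluded")
        ax.plot(kept["theta"], kept["ratio"], "o", color="C0", label="fit points")
        xs = np.linspace(kept["theta"].min(), kept["theta"].max(), 50)
        ax.plot(xs, self.intercept + self.K * xs, "-", color="C1",
                label=f"K={self.K:.4f} min$^{{-1}}$")
        ax.set_xlabel("normalized time $\\theta$ (min)")
        ax.set_ylabel("tissue / plasma activity")
        ax.legend()
        return ax


def patlak_fit(
    tac: TimeActivityCurve,
    ipf: PlasmaInputFunction,
    t_star: float = 10.0,
    weighting: str = "uniform",
) -> PatlakResults:
    """Functional wrapper: ``PatlakModel(tac, ipf, t_star, weighting).fit()``."""
    return PatlakModel(tac, ipf, t_star=t_star, weighting=weighting).fit()


@dataclass(frozen=True)
class MetabolicRate:
    """Cerebral metabolic rate derived from a Patlak rate constant."""

    cmr: float  # umol/100 g/min
    lumped_constant: float
    tissue_density: float  # g/mL

    def __float__(self) -> float:
        return self.cmr


def cmr_from_k(K: float, cp_met: float, lc: float, density: float = 1.0) -> MetabolicRate:
    """CMR = 100 * K * Cp / (LC * rho), in umol/100 g/min.

    Parameters
    ----------
    K : float
        Net influx rate constant (min^-1, per mL tissue).
    cp_met : float
        Plasma concentration of the native substrate (umol/mL).
    lc : float
        Lumped constant translating tracer-analog uptake into native
        substrate metabolism (0.8 glucose, 1.0 acetoacetate).
    density : float
        Tissue density (g/mL); with the default 1.0 the per-mL rate is
        reported per 100 g via the explicit factor 100.
    """
    if lc <= 0:
        raise ValueError("lumped constant must be positive")
    if density <= 0:
        raise ValueError("tissue density must be positive")
    if cp_met <= 0:
        raise ValueError("plasma metabolite concentration must be positive")
    return MetabolicRate(cmr=100.0 * K * cp_met / (lc * density), lumped_constant=lc, tissue_density=density)


def fit_regional_k(
    regional_tacs,
    ipf: PlasmaInputFunction,
    t_star: float = 10.0,
    weighting: str = "uniform",
    atlas=None,
) -> pd.DataFrame:
    """Patlak fit per region.

    Parameters
    ----------
    regional_tacs : mapping region_id -> TimeActivityCurve, or tuple
        Either regional mean TACs keyed by region id, or
        ``(dynamic_4d, label_volume, schedule)`` from which regional mean
        TACs are first extracted (frames stacked on the last axis;
        voxels that are NaN in a frame are ignored for that frame).
    atlas : RegionAtlas, optional
        Adds region names and enforces that every atlas region appears.

    Returns
    -------
    DataFrame with one row per region: region_id, region, K_per_min,
    intercept, r2, n_points, t_star, flagged, note.  Regions whose fit is
    undefined are flagged, never silently dropped.
    """
    if isinstance(regional_tacs, tuple):
        dynamic, labels, schedule = regional_tacs
        regional_tacs = _extract_regional_tacs(dynamic, labels, schedule)

    ids = sorted(regional_tacs)
    if atlas is not None:
        missing = [r.id for r in atlas.regions if r.id not in regional_tacs]
        ids = [r.id for r in atlas.regions if r.id in regional_tacs] + missing
    rows = []
    for rid in ids:
        name = atlas.name_of(rid) if atlas is not None else str(rid)
        tac = regional_tacs.get(rid)
        if tac is None:
            rows.append(dict(region_id=rid, region=name, K_per_min=np.nan, intercept=np.nan,
                             r2=np.nan, n_points=0, t_star=t_star, flagged=True, note="missing region"))
            continue
        try:
            res = patlak_fit(tac, ipf, t_star=t_star, weighting=weighting)
        except PatlakFitError as exc:
            rows.append(dict(region_id=rid, region=name, K_per_min=np.nan, intercept=np.nan,
                             r2=np.nan, n_points=0, t_star=t_star, flagged=True, note=str(exc)))
            continue
        flagged = res.K < 0
        rows.append(dict(region_id=rid, region=name, K_per_min=res.K, intercept=res.intercept,
                         r2=res.r_squared, n_points=res.n_points, t_star=t_star,
                         flagged=bool(flagged), note="negative K" if flagged else ""))
    return pd.DataFrame(rows)


def _extract_regional_tacs(dynamic: np.ndarray, labels: np.ndarray, schedule: FrameSchedule):
    """Mean TAC per label from a 4D image (x, y, z, frame)."""
    dynamic = np.asarray(dynamic, dtype=float)
    labels = np.asarray(labels)
    if dynamic.shape[:-1] != labels.shape:
        raise ValueError("dynamic image grid does not match label volume")
    if dynamic.shape[-1] != schedule.n_frames:
        raise ValueError("frame count mismatch between image and schedule")
    out = {}
    for rid in np.unique(labels):
        if rid == 0:
            continue
        mask = labels == rid
        vox = dynamic[mask]  # (n_vox, n_frames)
        with np.errstate(invalid="ignore"):
            means = np.nanmean(vox, axis=0)
        out[int(rid)] = TimeActivityCurve(schedule, np.nan_to_num(means, nan=0.0))
    return out
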