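"""Body-mass dynamics and lunar timing of life-history events.

Capture-table analyses: body masses are first corrected for gizzard
contents (a full gizzard adds ~12 g of food mass that is not body
reserve), fuel deposition rates come from first-to-last corrected mass
change of repeatedly captured birds, the onset of autumn fueling (or
of molt) is a two-segment breakpoint fit on a seasonal score trend,
and lunar synchronisation is quantified two ways: a phase-shift scan
that refits a mixed model against time-shifted moon illumination and
picks the shift maximising conditional R², and a circular
kernel-density peak of event dates on the 29.53-day lunar cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date as Date
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd

from . import ephemeris
from .astro import SYNODIC_MONTH_DAYS

__all__ = [
    "CaptureRecord",
    "PhaseScanResult",
    "EventTimingResult",
    "BreakpointResult",
    "gizzard_corrected_mass",
    "fuel_deposition_rate",
    "breakpoint_onset",
    "phase_shift_scan",
    "event_timing_vs_moon",
]


@dataclass(frozen=True)
class CaptureRecord:
    """One trapping event."""

    bird_id: str
    timestamp: datetime
    mass: float
    gizzard_score: int
    fat_score: int
    brood_patch: int
    n_molt: int = 0
    sex: str = ""

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if not 0 <= self.gizzard_score <= 4:
            raise ValueError("gizzard score must be 0–4")
        if not 0 <= self.fat_score <= 6:
            raise ValueError("fat score must be 0–6")
        if not 0 <= self.brood_patch <= 5:
            raise ValueError("brood patch score must be 0–5")
        if not 0 <= self.n_molt <= 30:
            raise ValueError("molt count must be 0–30")


def gizzard_corrected_mass(
    mass: float, gizzard_score: int, Mgimax: float = 11.72
) -> float:
    """Body mass minus estimated gizzard-content mass.

    Content is assumed linear in the 0–4 palpation score: a score-s
    gizzard holds (s/4)·Mgimax grams of food.
    """
    if not 0 <= gizzard_score <= 4:
        raise ValueError("gizzard score must be 0–4")
    return mass - (gizzard_score / 4.0) * Mgimax


def fuel_deposition_rate(
    captures: pd.DataFrame,
    Mgimax: float = 11.72,
    window: tuple[Date, Date] | None = None,
) -> pd.DataFrame:
    """Per-bird fuel deposition rate (g/day) from repeat captures.

    Within the fueling window, each bird's rate is the change in
    gizzard-corrected mass between its first and last capture divided
    by the days elapsed — insensitive to intermediate captures.
    Birds with any incubation/gravid record (brood patch score 3) are
    excluded, as are birds with fewer than two usable captures.

    Parameters
    ----------
    captures : DataFrame with columns bird_id, timestamp, mass,
        gizzard_score, brood_patch.

    Returns
    -------
    DataFrame with bird_id, n_captures, interval_days, fdr.
    """
    df = captures.copy()
    ts = pd.to_datetime(df["timestamp"], utc=True)
    if window is not None:
        lo, hi = window
        keep = (ts.dt.date >= lo) & (ts.dt.date <= hi)
        df, ts = df[keep], ts[keep]
    df = df.assign(_ts=ts)
    rows = []
    for bird, sub in df.groupby("bird_id"):
        if (sub["brood_patch"] == 3).any():
            continue  # breeding mass confound
        sub = sub.sort_values("_ts")
        if len(sub) < 2:
            continue
        first, last = sub.iloc[0], sub.iloc[-1]
        days = (last["_ts"] - first["_ts"]).total_seconds() / 86400.0
        if days <= 0:
            continue
        m0 = gizzard_corrected_mass(first["mass"], int(first["gizzard_score"]), Mgimax)
        m1 = gizzard_corrected_mass(last["mass"], int(last["gizzard_score"]), Mgimax)
        rows.append(
            {
                "bird_id": bird,
                "n_captures": len(sub),
                "interval_days": days,
                "fdr": (m1 - m0) / days,
            }
        )
    return pd.DataFrame(rows, columns=["bird_id", "n_captures", "interval_days", "fdr"])


@dataclass(frozen=True)
class BreakpointResult:
    day: float
    rss: float
    candidates: np.ndarray
    rss_grid: np.ndarray
    flat: bool


def breakpoint_onset(days, scores, min_points_per_side: int = 2) -> BreakpointResult:
    """Two-segment continuous least-squares breakpoint on a seasonal trend.

    Fits score ~ 1 + day + max(0, day − bp) at every candidate
    breakpoint (interior observed days with at least
    `min_points_per_side` points on each side) and returns the day
    minimising the residual sum of squares.  A flat RSS profile (pure
    linear trend, no identifiable break) triggers a warning and
    returns the candidate endpoint.
    """
    x = np.asarray(days, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.size < 2 * min_points_per_side + 1 or x.size < 10:
        raise ValueError("need at least 10 points spanning the candidate range")
    order = np.argsort(x)
    x, y = x[order], y[order]
    uniq = np.unique(x)
    candidates = np.array(
        [
            c
            for c in uniq
            if (x < c).sum() >= min_points_per_side
            and (x > c).sum() >= min_points_per_side
        ]
    )
    if candidates.size == 0:
        raise ValueError("no interior candidate breakpoints")
    rss_grid = np.empty(candidates.size)
    for i, c in enumerate(candidates):
        X = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - c)])
        _, res, _, _ = np.linalg.lstsq(X, y, rcond=None)
        if res.size:
            rss_grid[i] = res[0]
        else:
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            rss_grid[i] = float(np.sum((y - X @ beta) ** 2))
    spread = rss_grid.max() - rss_grid.min()
    flat = spread <= 1e-9 * max(1.0, rss_grid.max())
    if flat:
        warnings.warn("RSS profile is flat: no identifiable breakpoint")
        i_best = len(candidates) - 1
    else:
        i_best = int(np.argmin(rss_grid))
    return BreakpointResult(
        day=float(candidates[i_best]),
        rss=float(rss_grid[i_best]),
        candidates=candidates,
        rss_grid=rss_grid,
        flat=flat,
    )


# ---------------------------------------------------------------------------
# Lunar phase-shift scan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhaseScanResult:
    shifts: np.ndarray
    conditional_r2: np.ndarray
    best_shift: int
    no_signal: bool
    failed_shifts: tuple[int, ...]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"shift": self.shifts, "cond_r2": self.conditional_r2})


def _conditional_r2_mixedlm(result) -> float:
    """Nakagawa–Schielzeth conditional R² for a fitted MixedLM.

    (fixed-effect variance + random-intercept variance) over the total
    of fixed, random and residual variances.
    """
    fixed = result.model.exog @ result.fe_params
    var_f = float(np.var(fixed))
    var_re = float(np.trace(np.atleast_2d(result.cov_re)))  # already data-scale
    var_e = float(result.scale)
    return (var_f + var_re) / (var_f + var_re + var_e)


def phase_shift_scan(
    response,
    dates,
    groups=None,
    max_shift: int = 29,
    flat_epsilon: float = 0.05,
) -> PhaseScanResult:
    """Scan integer day-shifts of the moon signal for the best model fit.

    For each shift s in 0..max_shift the illuminated moon fraction is
    evaluated at (date − s days) and the model
    ``response ~ moon_fraction`` is refit — a linear mixed model with a
    random intercept when `groups` is given (bird or year identity),
    plain least squares otherwise.  The conditional R² (variance
    explained by fixed plus random effects) is recorded per shift and
    the smallest shift attaining the maximum wins.  A scan whose R²
    range is below `flat_epsilon` is flagged `no_signal` (response
    carries no detectable lunar periodicity).  Shifts where the fit
    fails to converge are excluded from the argmax.
    """
    y = np.asarray(response, dtype=float)
    dts = [
        d
        if isinstance(d, datetime)
        else datetime(d.year, d.month, d.day, tzinfo=timezone.utc)
        for d in dates
    ]
    if len(y) != len(dts):
        raise ValueError("response and dates differ in length")
    shifts = np.arange(0, max_shift + 1)
    r2 = np.full(shifts.size, np.nan)
    failed = []
    for s in shifts:
        x = np.array(
            [ephemeris.moon_illumination(d - timedelta(days=int(s))) for d in dts]
        )
        try:
            r2[s] = _fit_r2(y, x, groups)
        except Exception:
            failed.append(int(s))
    valid = ~np.isnan(r2)
    if not valid.any():
        raise RuntimeError("model failed to converge at every shift")
    best = int(shifts[valid][np.argmax(r2[valid])])
    no_signal = float(np.nanmax(r2) - np.nanmin(r2)) < flat_epsilon
    return PhaseScanResult(
        shifts=shifts,
        conditional_r2=r2,
        best_shift=best,
        no_signal=no_signal,
        failed_shifts=tuple(failed),
    )


def _fit_r2(y: np.ndarray, x: np.ndarray, groups) -> float:
    if groups is None:
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        tot = np.sum((y - y.mean()) ** 2)
        if tot == 0:
            return 0.0
        return 1.0 - float(np.sum(resid**2) / tot)
    import statsmodels.api as sm

    X = np.column_stack([np.ones_like(x), x])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=np.asarray(groups))
        result = model.fit(reml=True, method="lbfgs")
    return _conditional_r2_mixedlm(result)


# ---------------------------------------------------------------------------
# Circular timing of events on the lunar cycle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EventTimingResult:
    cycle_days: np.ndarray
    grid: np.ndarray
    density: np.ndarray
    peak_day: float
    rayleigh_p: float


def event_timing_vs_moon(
    event_dates,
    reference_full_moons,
    bandwidth_days: float = 2.0,
) -> EventTimingResult:
    """Distribution of events over the lunar cycle and its peak day.

    Events are mapped to days-since-full-moon using, for each event,
    the most recent reference full moon; a wrapped-Gaussian kernel
    density (period 29.53 days, bandwidth 2 days) is evaluated on a
    fine grid and its argmax is the peak.  A Rayleigh test of circular
    uniformity gives `rayleigh_p`: large values mean no detectable
    clustering, i.e. no meaningful peak.
    """
    refs = reference_full_moons
    if isinstance(refs, (Date, datetime)):
        refs = [refs]
    refs = sorted(
        r if isinstance(r, datetime) else datetime(r.year, r.month, r.day, tzinfo=timezone.utc)
        for r in refs
    )
    cycle_days = []
    for ev in event_dates:
        evdt = (
            ev
            if isinstance(ev, datetime)
            else datetime(ev.year, ev.month, ev.day, tzinfo=timezone.utc)
        )
        if evdt.tzinfo is None:
            evdt = evdt.replace(tzinfo=timezone.utc)
        past = [r for r in refs if r <= evdt]
        ref = past[-1] if past else refs[0]
        cycle_days.append(ephemeris.lunar_cycle_day(evdt, ref))
    cd = np.asarray(cycle_days)
    if cd.size == 0:
        raise ValueError("no events")
    period = SYNODIC_MONTH_DAYS
    grid = np.arange(0.0, period, 0.05)
    # wrapped Gaussian kernel: sum over nearest period images
    diff = grid[:, None] - cd[None, :]
    diff = (diff + period / 2) % period - period / 2
    density = np.exp(-0.5 * (diff / bandwidth_days) ** 2).sum(axis=1)
    density /= density.sum() * 0.05
    peak = float(grid[int(np.argmax(density))])
    theta = 2 * np.pi * cd / period
    n = cd.size
    R = float(np.abs(np.mean(np.exp(1j * theta))))
    z = n * R**2
    p = np.exp(-z) * (1 + (2 * z - z**2) / (4 * n)) if n >= 2 else 1.0
    return EventTimingResult(
        cycle_days=cd,
        grid=grid,
        density=density,
        peak_day=peak,
        rayleigh_p=float(np.clip(p, 0.0, 1.0)),
    )
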