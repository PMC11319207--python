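"""Confined-diffusion analysis of 2D single-particle tracks.

Per-track mean squared displacement (all overlapping frame pairs per
lag) is fitted with the circle-confined diffusion model

    MSD(t) = RoC^2 * (1 - exp(-4 * D * t / RoC^2)) + offset,

whose plateau RoC^2 is the radius of confinement explored by a bound
molecule, D the short-timescale diffusion coefficient and the offset
the localization-precision floor.  Fits are filtered (track length,
squared residual norm, RoC cap) before the condition-level comparison,
which is a differential of empirical cumulative RoC distributions:
deltaC(r) = C_control(r) - C_depleted(r), positive where depletion
shifted the RoC distribution toward larger radii.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .types import Track, TrackSet

__all__ = [
    "MSDCurve",
    "RoCFit",
    "FitFilterReport",
    "compute_msd",
    "confined_msd_model",
    "fit_confined",
    "fit_trackset",
    "filter_fits",
    "roc_cumulative_delta",
]


@dataclass
class MSDCurve:
    lags_s: np.ndarray
    msd_um2: np.ndarray
    n_disp: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lags_s) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd_um2 < 0):
            raise ValueError("MSD values must be non-negative")


@dataclass
class RoCFit:
    track_id: str
    roc_um: float
    d_um2s: float
    offset_um2: float
    resnorm: float  # sum of squared residuals, um^4
    track_len: int
    converged: bool = True


@dataclass
class FitFilterReport:
    n_in: int
    n_out: int
    n_short: int
    n_resnorm: int
    n_roc: int
    n_failed: int


def compute_msd(track: Track, max_lag_frames: int | None = None) -> MSDCurve:
    """Time-averaged MSD over all overlapping displacement pairs per lag.

    Lags are taken from frame-index differences so tracker gaps
    contribute to the correct lag; lags with no pairs are omitted.
    """
    frames = track.frames
    max_lag = int(frames[-1] - frames[0]) if max_lag_frames is None else max_lag_frames
    index_of = {int(f): i for i, f in enumerate(frames)}
    lags, msds, ns = [], [], []
    for k in range(1, max_lag + 1):
        pairs = [
            (i, index_of[int(f) + k])
            for f, i in ((f, index_of[int(f)]) for f in frames)
            if int(f) + k in index_of
        ]
        if not pairs:
            continue
        i0 = np.array([p[0] for p in pairs])
        i1 = np.array([p[1] for p in pairs])
        disp = track.xy[i1] - track.xy[i0]
        msds.append(float((disp**2).sum(axis=1).mean()))
        lags.append(k * track.dt)
        ns.append(len(pairs))
    return MSDCurve(
        lags_s=np.asarray(lags),
        msd_um2=np.asarray(msds),
        n_disp=np.asarray(ns, dtype=int),
    )


def confined_msd_model(
    t: np.ndarray, roc: float, d: float, offset: float
) -> np.ndarray:
    """Circle-confined diffusion MSD with localization offset."""
    roc2 = roc**2
    return roc2 * (1.0 - np.exp(-4.0 * d * t / roc2)) + offset


def fit_confined(
    msd: MSDCurve, track_id: str = "", track_len: int = 0
) -> RoCFit:
    """Nonlinear least-squares fit of the confined model to one MSD curve.

    All three parameters are constrained non-negative.  Initial guesses:
    offset0 = MSD at the first lag, RoC0 = sqrt(max(MSD) - offset0),
    D0 from the initial slope.  Non-convergence yields a flagged fit
    with NaN parameters.
    """
    t, y = msd.lags_s, msd.msd_um2
    if len(t) < 3:
        raise ValueError("need at least 3 lags to fit the confined model")
    offset0 = float(y[0])
    roc0 = float(np.sqrt(max(y.max() - offset0, 1e-6)))
    slope = (y[1] - y[0]) / (t[1] - t[0])
    d0 = float(max(slope / 4.0, 1e-6))
    try:
        popt, _ = scipy.optimize.curve_fit(
            confined_msd_model,
            t,
            y,
            p0=[roc0, d0, max(offset0, 0.0)],
            bounds=([1e-9, 0.0, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=10_000,
        )
    except (RuntimeError, ValueError):
        return RoCFit(
            track_id=track_id,
            roc_um=float("nan"),
            d_um2s=float("nan"),
            offset_um2=float("nan"),
            resnorm=float("nan"),
            track_len=track_len,
            converged=False,
        )
    residuals = y - confined_msd_model(t, *popt)
    return RoCFit(
        track_id=track_id,
        roc_um=float(popt[0]),
        d_um2s=float(popt[1]),
        offset_um2=float(popt[2]),
        resnorm=float((residuals**2).sum()),
        track_len=track_len,
        converged=True,
    )


def fit_trackset(
    ts: TrackSet,
    max_lag_frames: int | None = 20,
    min_track_len: int = 5,
) -> list[RoCFit]:
    """MSD + confined fit per track; tracks shorter than
    ``min_track_len`` frames are skipped before fitting."""
    fits = []
    for tr in ts.tracks:
        if len(tr) < min_track_len:
            continue
        lag_cap = (
            min(len(tr) - 1, max_lag_frames)
            if max_lag_frames is not None
            else None
        )
        msd = compute_msd(tr, max_lag_frames=lag_cap)
        if len(msd.lags_s) < 3:
            continue
        fits.append(fit_confined(msd, track_id=tr.track_id, track_len=len(tr)))
    return fits


def filter_fits(
    fits: list[RoCFit],
    min_track_len: int = 5,
    max_resnorm: float = 1e-5,
    max_roc_um: float = 0.5,
) -> tuple[list[RoCFit], FitFilterReport]:
    """Apply the fit-quality filters: track length >= 5 frames, squared
    residual norm <= 1e-5 um^4 and RoC <= 0.5 um (500 nm)."""
    kept = []
    n_short = n_res = n_roc = n_fail = 0
    for f in fits:
        if not f.converged or not np.isfinite(f.roc_um):
            n_fail += 1
            continue
        if f.track_len < min_track_len:
            n_short += 1
            continue
        if f.resnorm > max_resnorm:
            n_res += 1
            continue
        if f.roc_um > max_roc_um:
            n_roc += 1
            continue
        kept.append(f)
    return kept, FitFilterReport(
        n_in=len(fits),
        n_out=len(kept),
        n_short=n_short,
        n_resnorm=n_res,
        n_roc=n_roc,
        n_failed=n_fail,
    )


def roc_cumulative_delta(
    rocs_ctrl: np.ndarray,
    rocs_dep: np.ndarray,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Empirical RoC CDFs on a shared grid and their differential.

    deltaC(r) = C_ctrl(r) - C_dep(r); positive values mean the depleted
    condition shifted RoC toward larger radii.  Returns
    (grid, C_ctrl, C_dep, deltaC).
    """
    rocs_ctrl = np.asarray(rocs_ctrl, dtype=float)
    rocs_dep = np.asarray(rocs_dep, dtype=float)
    if len(rocs_ctrl) == 0 or len(rocs_dep) == 0:
        raise ValueError("both RoC sets must be non-empty")
    if grid is None:
        hi = max(rocs_ctrl.max(), rocs_dep.max())
        grid = np.linspace(0.0, hi, 201)
    grid = np.asarray(grid, dtype=float)
    c_ctrl = np.searchsorted(np.sort(rocs_ctrl), grid, side="right") / len(rocs_ctrl)
    c_dep = np.searchsorted(np.sort(rocs_dep), grid, side="right") / len(rocs_dep)
    return grid, c_ctrl, c_dep, c_ctrl - c_dep
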