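"""Kymograph analysis: peak tracking, speed fitting, split classification.

The position of a subpopulation's pulse at each saved instant is the
location of its density maximum (with parabolic sub-cell refinement); the
pulse speed is the least-squares slope of position against time after
discarding an initial transient.  A two-species run is classified as
*split* when the inter-species peak separation exceeds a multiple of the
mean pulse width and keeps growing over the final window — the signature of
the mixture being beyond the critical fast fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CM_S_TO_UM_S, ModelParams
from .simulate import Grid, Kymograph, SchemeConfig, run

__all__ = [
    "PeakTrack",
    "SpeedFit",
    "SplitResult",
    "track_peak",
    "fit_speed",
    "classify_split",
    "sweep_phi",
]


@dataclass(frozen=True)
class PeakTrack:
    """Per-frame pulse positions (cm); NaN where the frame has no mass."""

    positions: np.ndarray
    tie_flags: np.ndarray


@dataclass(frozen=True)
class SpeedFit:
    """Least-squares pulse speed from a position track."""

    speed: float  # cm/s
    intercept: float
    rms_residual: float
    n_points: int
    transient_discarded: float

    @property
    def speed_um_s(self) -> float:
        return self.speed * CM_S_TO_UM_S


@dataclass(frozen=True)
class SplitResult:
    """Outcome of the single-pulse / split classification."""

    classification: str  # "single" or "split"
    separation: np.ndarray  # |peak_1 - peak_2| per frame (cm)
    mean_fwhm: float  # mean pulse width over the final window (cm)
    threshold: float  # separation threshold actually applied (cm)


def track_peak(kymo: Kymograph, species: int) -> PeakTrack:
    """Trace the density maximum of one species through the kymograph.

    Ties (plateaus) resolve to the leftmost maximal cell and are flagged;
    interior maxima are refined to sub-cell precision by fitting a parabola
    through the three cells around the maximum.  All-zero frames yield NaN.
    """
    dens = kymo.density(species)
    n_frames, n_cells = dens.shape
    pos = np.full(n_frames, np.nan)
    ties = np.zeros(n_frames, dtype=bool)
    for n in range(n_frames):
        row = dens[n]
        top = row.max()
        if top <= 0.0:
            continue
        k = int(np.argmax(row))  # argmax is leftmost on ties
        ties[n] = np.count_nonzero(row == top) > 1
        p = kymo.x[k]
        if 0 < k < n_cells - 1 and not ties[n]:
            y0, y1, y2 = row[k - 1], row[k], row[k + 1]
            denom = y0 - 2.0 * y1 + y2
            if denom < 0.0:
                p += 0.5 * (y0 - y2) / denom * kymo.dx
        pos[n] = p
    return PeakTrack(positions=pos, tie_flags=ties)


def fit_speed(
    positions: np.ndarray,
    times: np.ndarray,
    transient_frac: float = 0.3,
) -> SpeedFit:
    """Least-squares slope of the post-transient position track.

    The first ``transient_frac`` of frames is discarded (the pulse needs
    time to form and detach from the wall); NaN positions are dropped.
    Raises when fewer than 3 usable points remain.
    """
    positions = np.asarray(positions, dtype=float)
    times = np.asarray(times, dtype=float)
    start = int(np.floor(transient_frac * len(times)))
    t, p = times[start:], positions[start:]
    keep = np.isfinite(p)
    t, p = t[keep], p[keep]
    if len(t) < 3:
        raise ValueError(f"speed fit needs >= 3 points, got {len(t)}")
    slope, intercept = np.polyfit(t, p, 1)
    resid = p - (slope * t + intercept)
    return SpeedFit(
        speed=float(slope),
        intercept=float(intercept),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        n_points=len(t),
        transient_discarded=transient_frac,
    )


def _fwhm(x: np.ndarray, row: np.ndarray) -> float:
    """Full width at half maximum by linear interpolation around the peak."""
    top = row.max()
    if top <= 0.0:
        return np.nan
    half = 0.5 * top
    k = int(np.argmax(row))
    above = row >= half

    def edge(direction: int) -> float:
        j = k
        while 0 <= j + direction < len(row) and above[j + direction]:
            j += direction
        jn = j + direction
        if jn < 0 or jn >= len(row):
            return x[j]
        # linear interpolation between the last point above and first below
        f = (row[j] - half) / (row[j] - row[jn])
        return x[j] + f * (x[jn] - x[j])

    return edge(+1) - edge(-1)


def classify_split(
    kymo: Kymograph,
    *,
    threshold: float = 2.0,
    window_frac: float = 0.2,
) -> SplitResult:
    """Decide whether the two subpopulations travel as one pulse or two.

    Split requires the peak separation to exceed ``threshold`` times the
    mean pulse FWHM throughout the final ``window_frac`` of frames *and* to
    grow across that window (transient wobble does not count).
    """
    p1 = track_peak(kymo, 0).positions
    p2 = track_peak(kymo, 1).positions
    sep = np.abs(p1 - p2)
    n = kymo.n_frames
    start = max(0, int(np.floor((1.0 - window_frac) * n)))
    widths = []
    for species in (0, 1):
        dens = kymo.density(species)
        for j in range(start, n):
            widths.append(_fwhm(kymo.x, dens[j]))
    mean_fwhm = float(np.nanmean(widths)) if widths else np.nan
    window = sep[start:]
    usable = np.isfinite(window)
    thresh = threshold * mean_fwhm
    sustained = bool(np.all(window[usable] > thresh)) if usable.any() else False
    growing = False
    if usable.sum() >= 2:
        idx = np.arange(len(window))[usable]
        growing = bool(np.polyfit(idx, window[usable], 1)[0] > 0.0)
    label = "split" if (sustained and growing) else "single"
    return SplitResult(
        classification=label,
        separation=sep,
        mean_fwhm=mean_fwhm,
        threshold=float(thresh),
    )


def sweep_phi(
    params: ModelParams,
    grid: Grid,
    cfg: SchemeConfig,
    phi_grid,
    *,
    transient_frac: float = 0.3,
) -> pd.DataFrame:
    """Simulate each fast-fraction value and tabulate fitted speeds.

    Returns a frame with columns ``phi_red``, ``speed_green_um_s``,
    ``speed_red_um_s`` and ``classification``; a species with zero mass
    gets NaN speed, and pure runs (phi in {0, 1}) are classified single.
    """
    rows = []
    for phi in phi_grid:
        p = params.with_phi(float(phi))
        kymo = run(p, grid, cfg)
        speeds = []
        for species, mass in ((0, p.mix.M1), (1, p.mix.M2)):
            if mass <= 0.0:
                speeds.append(np.nan)
                continue
            track = track_peak(kymo, species)
            speeds.append(
                fit_speed(track.positions, kymo.times, transient_frac).speed
            )
        if p.mix.M1 > 0.0 and p.mix.M2 > 0.0:
            label = classify_split(kymo).classification
        else:
            label = "single"
        rows.append(
            {
                "phi_red": float(phi),
                "speed_green_um_s": speeds[0] * CM_S_TO_UM_S,
                "speed_red_um_s": speeds[1] * CM_S_TO_UM_S,
                "classification": label,
            }
        )
    return pd.DataFrame(rows)
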