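"""Intensity-carpet alignment and nanoscale inter-layer distance estimation.

An *intensity carpet* is a matrix whose columns are fluorescence line
profiles perpendicular to the apical membrane (the y axis), sampled
every 25 nm along the membrane axis.  Because the membrane stretches
and folds at the nanoscale, the layer apex drifts from column to
column; columns are first aligned to a reference column using the
paired correlation function

    pCF(dy) = <F(y, 0) F(y + dy, dr)> / (<F(y, 0)> <F(y, dr)>) - 1

where ``F(y, 0)`` is the reference profile, ``F(y, dr)`` the profile at
lateral distance ``dr``, and averages run over the y samples where both
profiles exist (no wrap-around).  ``argmax(pCF)``, refined to sub-bin
precision by a quadratic fit through the peak and its two neighbors,
gives the per-column shift; translating each column by the negative
shift aligns the carpet.

The signed distance between the two fluorescence layers is then read
per column from the paired cross-correlation function (same form, with
``F_1`` the reference-channel and ``F_2`` the test-channel profile of
the same aligned column).  Sign convention: negative distances point
toward the cytoplasm (smaller y), positive toward the lumen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

from nanolayers.containers import (
    GeometryError,
    InvalidParameterError,
    SuperResImage,
)

__all__ = [
    "IntensityCarpet",
    "AlignmentShifts",
    "AverageProfile",
    "DistanceDistribution",
    "extract_carpet",
    "pcf",
    "pccf",
    "refined_argmax",
    "align_carpet",
    "apply_shifts",
    "average_aligned_profile",
    "column_distances",
    "distance_distribution",
]


@dataclass
class IntensityCarpet:
    """Column-wise membrane-perpendicular line profiles of one channel.

    ``columns[i, c]`` is the intensity at perpendicular sample ``i`` of
    the column at lateral position ``c * column_width_nm``.  The y axis
    grows toward the lumen.
    """

    columns: np.ndarray  # (ny, ncol)
    row_spacing_nm: float
    column_width_nm: float = 25.0
    reference_index: int = 0
    channel_label: str = ""
    replicate_id: str = ""
    valid: np.ndarray | None = None  # per-column flag, set by alignment

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim != 2:
            raise InvalidParameterError("carpet columns must form a 2-D array")
        if not (self.row_spacing_nm > 0 and self.column_width_nm > 0):
            raise InvalidParameterError("spacings must be > 0")
        if not (0 <= self.reference_index < self.columns.shape[1]):
            raise InvalidParameterError("reference_index out of range")
        if self.valid is None:
            self.valid = np.ones(self.columns.shape[1], dtype=bool)

    @property
    def n_columns(self) -> int:
        return self.columns.shape[1]

    @property
    def y_nm(self) -> np.ndarray:
        return (np.arange(self.columns.shape[0]) + 0.5) * self.row_spacing_nm


@dataclass
class AlignmentShifts:
    """Per-column shifts (nm) relative to the reference column."""

    shifts_nm: np.ndarray
    valid: np.ndarray
    reference_index: int
    method: str = "argmax(pCF)"


@dataclass
class AverageProfile:
    y_nm: np.ndarray
    mean: np.ndarray
    sem: np.ndarray | None
    n_replicates: int
    replicate_means: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class DistanceDistribution:
    """Signed per-column inter-layer distances with replicate structure."""

    distances: pd.DataFrame  # columns: replicate, column, distance_nm
    mean_nm: float
    sem_nm: float | None
    modes: list[tuple[float, float]]  # (location nm, relative weight)
    n_replicates: int
    reliable: bool


def extract_carpet(image: SuperResImage, rect_nm: tuple[float, float, float, float],
                   rotation_angle_deg: float = 0.0, column_width_nm: float = 25.0,
                   channel_label: str = "", replicate_id: str = "",
                   reference_index: int = 0) -> IntensityCarpet:
    """Rotate, crop and column-bin a ROI into an intensity carpet.

    ``rect_nm = (x0, y0, width, height)`` describes the ROI in the
    *rotated* frame where the membrane axis is horizontal; the image is
    resampled with bicubic interpolation on the grid obtained by
    rotating the ROI grid by ``-rotation_angle_deg`` about the ROI
    center (i.e. the angle is the rotation that was applied to make the
    membrane horizontal, as in interactive ROI rotation).  Pixel
    columns are then averaged into ``column_width_nm`` bins.
    """
    px = image.pixel_size_nm
    x0, y0, width, height = rect_nm
    ncol_px = int(round(width / px))
    nrow_px = int(round(height / px))
    if ncol_px < 1 or nrow_px < 1:
        raise InvalidParameterError("ROI must span at least one pixel")
    ratio = column_width_nm / px
    if abs(ratio - round(ratio)) > 1e-6 or round(ratio) < 1:
        raise InvalidParameterError(
            "column_width_nm must be an integer multiple of the pixel size")
    binf = int(round(ratio))

    xs = x0 + (np.arange(ncol_px) + 0.5) * px
    ys = y0 + (np.arange(nrow_px) + 0.5) * px
    gx, gy = np.meshgrid(xs, ys)
    theta = np.deg2rad(rotation_angle_deg)
    cx, cy = x0 + width / 2.0, y0 + height / 2.0
    # invert the rotation that made the membrane horizontal
    sx = cx + np.cos(theta) * (gx - cx) + np.sin(theta) * (gy - cy)
    sy = cy - np.sin(theta) * (gx - cx) + np.cos(theta) * (gy - cy)
    rows = sy / px - 0.5
    cols = sx / px - 0.5
    h, w = image.values.shape
    if (rows.min() < -0.5 or rows.max() > h - 0.5
            or cols.min() < -0.5 or cols.max() > w - 0.5):
        raise GeometryError("rotated ROI falls outside the image")
    sub = ndimage.map_coordinates(image.values, [rows, cols], order=3,
                                  mode="nearest")

    ncol = ncol_px // binf
    sub = sub[:, : ncol * binf].reshape(nrow_px, ncol, binf).mean(axis=2)
    return IntensityCarpet(columns=sub, row_spacing_nm=px,
                           column_width_nm=column_width_nm,
                           reference_index=reference_index,
                           channel_label=channel_label,
                           replicate_id=replicate_id)


def _paired_correlation(p_ref: np.ndarray, p_other: np.ndarray,
                        max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    p_ref = np.asarray(p_ref, dtype=float)
    p_other = np.asarray(p_other, dtype=float)
    if p_ref.shape != p_other.shape or p_ref.ndim != 1:
        raise InvalidParameterError("profiles must be equal-length 1-D arrays")
    n = len(p_ref)
    if p_ref.mean() == 0 or p_other.mean() == 0:
        raise InvalidParameterError("profile with zero mean: pCF undefined")
    max_lag = int(min(max_lag, n - 2))
    lags = np.arange(-max_lag, max_lag + 1)
    vals = np.full(len(lags), np.nan)
    for i, k in enumerate(lags):
        if k >= 0:
            a, b = p_ref[: n - k], p_other[k:]
        else:
            a, b = p_ref[-k:], p_other[: n + k]
        ma, mb = a.mean(), b.mean()
        if ma > 0 and mb > 0:
            vals[i] = (a * b).mean() / (ma * mb) - 1.0
    return lags, vals


def pcf(profile_ref: np.ndarray, profile_other: np.ndarray,
        max_lag: int = 40) -> tuple[np.ndarray, np.ndarray]:
    """Paired correlation function over symmetric lags (no wrap-around).

    Averages at each lag run over the overlapping samples only.  A lag
    whose overlap mean vanishes yields NaN; a constant profile yields 0
    at every lag.
    """
    return _paired_correlation(profile_ref, profile_other, max_lag)


def pccf(profile_1: np.ndarray, profile_2: np.ndarray,
         max_lag: int = 40) -> tuple[np.ndarray, np.ndarray]:
    """Paired cross-correlation function between the two channels.

    Identical functional form to :func:`pcf`; ``profile_1`` is the
    reference-channel profile and defines the zero of the distance
    axis.
    """
    return _paired_correlation(profile_1, profile_2, max_lag)


def refined_argmax(lags: np.ndarray, vals: np.ndarray) -> tuple[float, float]:
    """Sub-bin argmax by a quadratic through the peak and its neighbors.

    Returns ``(lag, value)``; the parabola vertex offset is clipped to
    half a bin.  Falls back to the integer argmax at the range edge.
    """
    if np.all(np.isnan(vals)):
        raise InvalidParameterError("correlation values are all undefined")
    i = int(np.nanargmax(vals))
    peak = float(vals[i])
    if 0 < i < len(vals) - 1 and np.isfinite(vals[i - 1]) and np.isfinite(vals[i + 1]):
        denom = vals[i - 1] - 2.0 * vals[i] + vals[i + 1]
        if denom < 0:
            delta = 0.5 * (vals[i - 1] - vals[i + 1]) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            return float(lags[i]) + delta, peak
    return float(lags[i]), peak


def align_carpet(carpet: IntensityCarpet, max_lag_nm: float = 1000.0,
                 peak_floor: float = 0.05,
                 ) -> tuple[AlignmentShifts, IntensityCarpet]:
    """Align every column to the reference column via argmax(pCF).

    Columns whose pCF maximum falls below ``peak_floor`` are flagged
    unalignable, left untranslated and excluded from downstream
    statistics.
    """
    ny = carpet.columns.shape[0]
    max_lag = int(min(np.floor(max_lag_nm / carpet.row_spacing_nm), ny // 2))
    ref = carpet.columns[:, carpet.reference_index]
    shifts = np.zeros(carpet.n_columns)
    valid = np.ones(carpet.n_columns, dtype=bool)
    for c in range(carpet.n_columns):
        if c == carpet.reference_index:
            continue
        lags, vals = pcf(ref, carpet.columns[:, c], max_lag)
        if np.all(np.isnan(vals)) or np.nanmax(vals) < peak_floor:
            valid[c] = False
            continue
        lag, _ = refined_argmax(lags, vals)
        shifts[c] = lag * carpet.row_spacing_nm
    result = AlignmentShifts(shifts_nm=shifts, valid=valid,
                             reference_index=carpet.reference_index)
    return result, apply_shifts(carpet, result)


def apply_shifts(carpet: IntensityCarpet, shifts: AlignmentShifts,
                 ) -> IntensityCarpet:
    """Translate each valid column by minus its shift (cubic interpolation).

    Out-of-range samples are filled with the column mean so that the
    overlap-normalized correlations are not biased by hard zeros.
    """
    out = carpet.columns.copy()
    for c in range(carpet.n_columns):
        if not shifts.valid[c]:
            continue
        s = shifts.shifts_nm[c] / carpet.row_spacing_nm
        if s != 0.0:
            col = carpet.columns[:, c]
            # out(y) = col(y + s): undo a peak displaced by +s bins
            out[:, c] = ndimage.shift(col, -s, order=3, mode="constant",
                                      cval=float(col.mean()))
    return IntensityCarpet(columns=out, row_spacing_nm=carpet.row_spacing_nm,
                           column_width_nm=carpet.column_width_nm,
                           reference_index=carpet.reference_index,
                           channel_label=carpet.channel_label,
                           replicate_id=carpet.replicate_id,
                           valid=shifts.valid.copy())


def average_aligned_profile(carpets: Sequence[IntensityCarpet]) -> AverageProfile:
    """Mean profile with SEM across cellular replicates.

    Columns are pooled (mean over valid columns) within each replicate
    first; the reported mean and SEM are then taken across the
    replicate means, so the confidence band reflects cell-to-cell
    variability rather than the number of columns.
    """
    by_rep: dict[str, list[np.ndarray]] = {}
    for c in carpets:
        by_rep.setdefault(c.replicate_id, []).append(
            c.columns[:, c.valid].mean(axis=1))
    rep_means = {k: np.mean(v, axis=0) for k, v in by_rep.items()}
    arr = np.stack(list(rep_means.values()))
    mean = arr.mean(axis=0)
    n = len(rep_means)
    sem = arr.std(axis=0, ddof=1) / np.sqrt(n) if n >= 2 else None
    return AverageProfile(y_nm=carpets[0].y_nm, mean=mean, sem=sem,
                          n_replicates=n, replicate_means=rep_means)


def column_distances(carpet_ref: IntensityCarpet, carpet_test: IntensityCarpet,
                     max_lag_nm: float = 1000.0, peak_floor: float = 0.05,
                     ) -> np.ndarray:
    """Per-column signed distance (nm) of channel 2 relative to channel 1.

    For each column shared by the two aligned carpets, the refined
    argmax of the pCCF between the reference-channel and test-channel
    profiles; NaN where either column is invalid or the correlation
    peak is below ``peak_floor``.
    """
    if carpet_ref.columns.shape != carpet_test.columns.shape:
        raise InvalidParameterError("carpets must share shape")
    ny = carpet_ref.columns.shape[0]
    max_lag = int(min(np.floor(max_lag_nm / carpet_ref.row_spacing_nm), ny // 2))
    out = np.full(carpet_ref.n_columns, np.nan)
    for c in range(carpet_ref.n_columns):
        if not (carpet_ref.valid[c] and carpet_test.valid[c]):
            continue
        lags, vals = pccf(carpet_ref.columns[:, c], carpet_test.columns[:, c],
                          max_lag)
        if np.all(np.isnan(vals)) or np.nanmax(vals) < peak_floor:
            continue
        lag, _ = refined_argmax(lags, vals)
        out[c] = lag * carpet_ref.row_spacing_nm
    return out


def _detect_modes(d: np.ndarray, prominence_frac: float = 0.10,
                  ) -> list[tuple[float, float]]:
    """KDE (Silverman bandwidth) modes with >= 10% relative prominence."""
    if len(d) < 3 or np.ptp(d) == 0:
        return [(float(np.mean(d)), 1.0)]
    kde = stats.gaussian_kde(d, bw_method="silverman")
    span = np.ptp(d)
    grid = np.linspace(d.min() - 0.25 * span, d.max() + 0.25 * span, 512)
    dens = kde(grid)
    peaks, _ = signal.find_peaks(dens, prominence=prominence_frac * dens.max())
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(dens))])
    heights = dens[peaks]
    weights = heights / heights.sum()
    return [(float(grid[p]), float(w)) for p, w in zip(peaks, weights)]


def distance_distribution(pairs: Sequence[tuple[IntensityCarpet, IntensityCarpet]],
                          max_lag_nm: float = 1000.0, peak_floor: float = 0.05,
                          min_columns: int = 24) -> DistanceDistribution:
    """Pool per-column pCCF distances over aligned carpet pairs.

    The summary mean and SEM are computed at the cellular-replicate
    level (one mean per ``replicate_id``); modes of the pooled
    distribution are detected by kernel density estimation.
    """
    rows = []
    for ref_c, test_c in pairs:
        d = column_distances(ref_c, test_c, max_lag_nm=max_lag_nm,
                             peak_floor=peak_floor)
        for col, val in enumerate(d):
            if np.isfinite(val):
                rows.append((ref_c.replicate_id, col, float(val)))
    df = pd.DataFrame(rows, columns=["replicate", "column", "distance_nm"])
    if len(df) < min_columns:
        raise InvalidParameterError(
            f"only {len(df)} usable columns (< {min_columns})")
    rep_means = df.groupby("replicate")["distance_nm"].mean()
    n_rep = len(rep_means)
    mean = float(rep_means.mean())
    sem = float(rep_means.std(ddof=1) / np.sqrt(n_rep)) if n_rep >= 2 else None
    return DistanceDistribution(
        distances=df, mean_nm=mean, sem_nm=sem,
        modes=_detect_modes(df["distance_nm"].to_numpy()),
        n_replicates=n_rep, reliable=n_rep >= 2)
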