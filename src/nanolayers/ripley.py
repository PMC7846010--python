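"""Intensity-weighted Ripley K statistics with CSR permutation envelopes.

The estimator treats every pixel of an intensity field (e.g. one 8-bit
grayscale channel of a super-resolved ROI) as a weighted event at the
pixel center.  For a radius ``r``,

    K(r) = A * sum_{i != j} w_i w_j e_i(r) 1(d_ij <= r) / (sum w)^2

with ``A`` the masked window area, ``d_ij`` the Euclidean center-to-
center distance, and ``e_i(r)`` the Besag edge-correction weight of the
center pixel: the ratio of the full disc area to the disc-inside-mask
area, both measured as pixel counts, so interior pixels have weight
exactly 1.  Under complete spatial randomness (CSR) ``K(r) ~ pi r^2``.

The null model is a within-mask permutation of the pixel intensities:
it preserves the intensity histogram exactly while destroying all
spatial structure.  ``K`` is recomputed for each permutation; the
per-radius mean and standard deviation normalize the observed curve to
the dimensionless ``K-tilde`` (zero mean, unit variance under CSR) and
the requested quantiles (default 1st/99th) form the acceptance
envelope.  Radii where K-tilde exceeds the upper envelope are labeled
``clustered``, below the lower envelope ``dispersed``, otherwise
``random``.  The scalar summary used for group comparisons is
``argmax(K-tilde)`` (ties broken toward the smaller radius).

Implementation: the interior part of the pair sum is an autocorrelation
and is evaluated for all radii at once with FFTs; only pixels whose
disc leaves the mask need the explicit Besag factor, and their disc
sums are evaluated with a numba kernel using row-cumulative-sum lookups.
The result is exactly (to float precision) the brute-force O(n^2) pair
sum, which is kept in :func:`k_bruteforce` as the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from numba import njit
from scipy import fft as sfft

from nanolayers.containers import InvalidParameterError, SuperResImage

__all__ = [
    "IntensityField",
    "RadiusGrid",
    "CsrNull",
    "KCurve",
    "RipleyEngine",
    "besag_edge_weights",
    "intensity_k_raw",
    "k_bruteforce",
    "build_csr_null",
    "normalize_k",
    "summarize_k",
    "analyze_field",
    "compare_argmax_groups",
]


@dataclass
class IntensityField:
    """A nonnegative pixel-weight image with an optional analysis mask."""

    values: np.ndarray
    pixel_size_nm: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidParameterError("field values must be 2-D")
        if np.any(self.values < 0):
            raise InvalidParameterError("field values must be >= 0")
        if not self.pixel_size_nm > 0:
            raise InvalidParameterError("pixel_size_nm must be > 0")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise InvalidParameterError("mask shape must match values")
        if not (self.values * self.mask).sum() > 0:
            raise InvalidParameterError("total masked weight must be > 0")

    @classmethod
    def from_image(cls, image: SuperResImage,
                   mask: np.ndarray | None = None) -> "IntensityField":
        return cls(values=image.values, pixel_size_nm=image.pixel_size_nm, mask=mask)


@dataclass
class RadiusGrid:
    """Uniform radius grid ``step, 2*step, ..., r_max`` in nm."""

    step_nm: float = 25.0
    r_max_nm: float = 2500.0

    def __post_init__(self) -> None:
        if not (self.step_nm > 0 and self.r_max_nm >= self.step_nm):
            raise InvalidParameterError("need 0 < step <= r_max")
        n = int(np.floor(self.r_max_nm / self.step_nm + 1e-9))
        self.radii_nm = self.step_nm * np.arange(1, n + 1)

    def validate_for(self, field: IntensityField) -> None:
        short_nm = min(field.values.shape) * field.pixel_size_nm
        if self.radii_nm[-1] > short_nm / 2 + 1e-9:
            raise InvalidParameterError(
                f"max radius {self.radii_nm[-1]:.0f} nm exceeds half the "
                f"shorter window side ({short_nm / 2:.0f} nm)")


@dataclass
class CsrNull:
    """Permutation-null specification and, once built, its statistics."""

    n_simulations: int = 200
    quantile_low: float = 0.01
    quantile_high: float = 0.99
    seed: int = 0
    # filled by build_csr_null
    radii_nm: np.ndarray | None = None
    mean: np.ndarray | None = None
    sd: np.ndarray | None = None
    q_low: np.ndarray | None = None
    q_high: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_simulations < 100:
            raise InvalidParameterError("n_simulations must be >= 100")
        if not (0.0 < self.quantile_low < self.quantile_high < 1.0):
            raise InvalidParameterError("need 0 < quantile_low < quantile_high < 1")


@dataclass
class KCurve:
    """K statistics over a radius grid with envelopes and classification."""

    radii_nm: np.ndarray
    k_raw: np.ndarray
    k_tilde: np.ndarray
    env_low: np.ndarray
    env_high: np.ndarray
    classification: np.ndarray  # str array: clustered / dispersed / random
    argmax_radius_nm: float
    argmax_value: float
    null: CsrNull | None = None
    meta: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# numba kernels

@njit(cache=True)
def _disc_sums_at(P, ys, xs, h_flat, h_ptr, r_idx, H, W):  # pragma: no cover
    """Disc sums of a row-cumsum table P (H, W+1) at the given pixels."""
    out = np.empty(len(ys))
    h0 = h_ptr[r_idx]
    t = h_ptr[r_idx + 1] - h0 - 1  # h given for dy = 0..t
    for k in range(len(ys)):
        y = ys[k]
        x = xs[k]
        s = 0.0
        for dy in range(-t, t + 1):
            yy = y + dy
            if yy < 0 or yy >= H:
                continue
            h = h_flat[h0 + (dy if dy >= 0 else -dy)]
            lo = x - h
            hi = x + h
            if lo < 0:
                lo = 0
            if hi > W - 1:
                hi = W - 1
            s += P[yy, hi + 1] - P[yy, lo]
        out[k] = s
    return out


@njit(cache=True)
def _band_terms(P, w, band_y, band_x, band_em1, band_ptr,
                h_flat, h_ptr, H, W):  # pragma: no cover
    """Boundary part of the pair sum: sum_i w_i (e_i(r)-1) (discsum_i - w_i)."""
    nr = len(band_ptr) - 1
    out = np.zeros(nr)
    for r in range(nr):
        h0 = h_ptr[r]
        t = h_ptr[r + 1] - h0 - 1
        acc = 0.0
        for k in range(band_ptr[r], band_ptr[r + 1]):
            y = band_y[k]
            x = band_x[k]
            s = 0.0
            for dy in range(-t, t + 1):
                yy = y + dy
                if yy < 0 or yy >= H:
                    continue
                h = h_flat[h0 + (dy if dy >= 0 else -dy)]
                lo = x - h
                hi = x + h
                if lo < 0:
                    lo = 0
                if hi > W - 1:
                    hi = W - 1
                s += P[yy, hi + 1] - P[yy, lo]
            acc += w[y, x] * band_em1[k] * (s - w[y, x])
        out[r] = acc
    return out


def _row_cumsum(w: np.ndarray) -> np.ndarray:
    P = np.zeros((w.shape[0], w.shape[1] + 1))
    np.cumsum(w, axis=1, out=P[:, 1:])
    return P


# ---------------------------------------------------------------------------

class RipleyEngine:
    """Precomputed geometry for repeated K evaluations on one mask/grid.

    Building the engine costs one pass over the mask; each subsequent
    :meth:`k` call (e.g. for a permutation of the weights) costs two
    FFTs plus the boundary kernel.
    """

    def __init__(self, mask: np.ndarray, radii_px: np.ndarray,
                 edge_correction: bool = True):
        mask = np.asarray(mask, dtype=bool)
        self.mask = mask
        self.H, self.W = mask.shape
        self.radii_px = np.asarray(radii_px, dtype=float)
        self.nr = len(self.radii_px)
        self.edge_correction = edge_correction
        self.n_mask = int(mask.sum())

        t_int = np.floor(self.radii_px + 1e-9).astype(np.int64)
        self.t_int = t_int
        R = int(t_int[-1])
        self.R = R

        # disc row half-widths per radius (dy = 0..t)
        h_list, h_ptr = [], [0]
        for t_r, t_i in zip(self.radii_px, t_int):
            dy = np.arange(t_i + 1)
            h_list.append(np.floor(np.sqrt(np.maximum(t_r ** 2 - dy ** 2, 0.0))
                                   + 1e-9).astype(np.int64))
            h_ptr.append(h_ptr[-1] + t_i + 1)
        self.h_flat = np.concatenate(h_list) if h_list else np.zeros(0, np.int64)
        self.h_ptr = np.asarray(h_ptr, dtype=np.int64)
        self.n_full = np.array([(2 * h + 1).sum() * 2 - (2 * h[0] + 1)
                                for h in h_list], dtype=np.int64)

        # FFT geometry for the autocorrelation window
        self.pH = sfft.next_fast_len(self.H + R, real=True)
        self.pW = sfft.next_fast_len(self.W + R, real=True)
        dy, dx = np.meshgrid(np.arange(-R, R + 1), np.arange(-R, R + 1),
                             indexing="ij")
        dist = np.hypot(dy, dx).ravel()
        bins = np.searchsorted(self.radii_px + 1e-9, dist, side="left")
        bins[dist == 0] = self.nr  # exclude self-pairs
        self.offset_bins = np.where(bins < self.nr, bins, self.nr)
        self._win_rows = np.r_[self.pH - R:self.pH, 0:R + 1]
        self._win_cols = np.r_[self.pW - R:self.pW, 0:R + 1]

        # boundary band: pixels whose disc leaves the mask, per radius
        Pm = _row_cumsum(mask.astype(float))
        ys, xs = np.nonzero(mask)
        ys = np.ascontiguousarray(ys.astype(np.int64))
        xs = np.ascontiguousarray(xs.astype(np.int64))
        band_y, band_x, band_em1, band_ptr = [], [], [], [0]
        for r in range(self.nr):
            n_in = _disc_sums_at(Pm, ys, xs, self.h_flat, self.h_ptr, r,
                                 self.H, self.W)
            n_in = np.round(n_in).astype(np.int64)
            sel = n_in < self.n_full[r]
            band_y.append(ys[sel])
            band_x.append(xs[sel])
            band_em1.append(self.n_full[r] / n_in[sel] - 1.0)
            band_ptr.append(band_ptr[-1] + int(sel.sum()))
        self.band_y = np.concatenate(band_y) if band_y else np.zeros(0, np.int64)
        self.band_x = np.concatenate(band_x) if band_x else np.zeros(0, np.int64)
        self.band_em1 = (np.concatenate(band_em1) if band_em1
                         else np.zeros(0, float))
        self.band_ptr = np.asarray(band_ptr, dtype=np.int64)

    def pair_sums(self, w: np.ndarray) -> np.ndarray:
        """Edge-corrected pair sums sum_{i!=j} w_i w_j e_i(r) per radius."""
        w = np.where(self.mask, w, 0.0)
        F = sfft.rfft2(w, s=(self.pH, self.pW))
        auto = sfft.irfft2(F * np.conj(F), s=(self.pH, self.pW))
        win = auto[np.ix_(self._win_rows, self._win_cols)].ravel()
        binned = np.bincount(self.offset_bins, weights=win,
                             minlength=self.nr + 1)[: self.nr]
        sums = np.cumsum(binned)
        if self.edge_correction and len(self.band_y):
            P = _row_cumsum(w)
            sums = sums + _band_terms(P, w, self.band_y, self.band_x,
                                      self.band_em1, self.band_ptr,
                                      self.h_flat, self.h_ptr, self.H, self.W)
        return sums

    def k(self, w: np.ndarray, pixel_size_nm: float) -> np.ndarray:
        """K(r) in nm² for one weight image."""
        w = np.where(self.mask, w, 0.0)
        total = w.sum()
        if not total > 0:
            raise InvalidParameterError("total masked weight must be > 0")
        area_nm2 = self.n_mask * pixel_size_nm ** 2
        return area_nm2 * self.pair_sums(w) / total ** 2


def _engine_for(field: IntensityField, grid: RadiusGrid,
                edge_correction: bool = True) -> RipleyEngine:
    grid.validate_for(field)
    return RipleyEngine(field.mask, grid.radii_nm / field.pixel_size_nm,
                        edge_correction=edge_correction)


def besag_edge_weights(mask: np.ndarray, radius_nm: float,
                       pixel_size_nm: float) -> np.ndarray:
    """Per-pixel Besag correction factors at one radius.

    The weight of an in-mask pixel is (number of lattice offsets within
    the disc) / (number of those falling inside the mask); it is exactly
    1 for pixels whose disc lies fully inside and grows toward 2 on a
    straight edge and 4 at a convex corner.  Off-mask pixels are NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    t = radius_nm / pixel_size_nm
    eng = RipleyEngine(mask, np.array([t]))
    out = np.full(mask.shape, np.nan)
    out[mask] = 1.0
    sl = slice(eng.band_ptr[0], eng.band_ptr[1])
    out[eng.band_y[sl], eng.band_x[sl]] = eng.band_em1[sl] + 1.0
    return out


def intensity_k_raw(field: IntensityField, grid: RadiusGrid,
                    edge_correction: bool = True) -> np.ndarray:
    """Edge-corrected, intensity-weighted K(r) in nm² over the grid."""
    eng = _engine_for(field, grid, edge_correction)
    return eng.k(field.values, field.pixel_size_nm)


def k_bruteforce(field: IntensityField, grid: RadiusGrid,
                 edge_correction: bool = True) -> np.ndarray:
    """O(n²) pair-sum oracle for :func:`intensity_k_raw` (small images only)."""
    grid.validate_for(field)
    mask = field.mask
    ys, xs = np.nonzero(mask)
    w = field.values[ys, xs]
    n = len(w)
    d = np.hypot(ys[:, None] - ys[None, :], xs[:, None] - xs[None, :])
    radii_px = grid.radii_nm / field.pixel_size_nm
    area_nm2 = n * field.pixel_size_nm ** 2
    total = w.sum()

    # full-disc lattice counts
    R = int(np.floor(radii_px[-1] + 1e-9))
    oy, ox = np.meshgrid(np.arange(-R, R + 1), np.arange(-R, R + 1), indexing="ij")
    od = np.hypot(oy, ox).ravel()

    out = np.empty(len(radii_px))
    for k, t in enumerate(radii_px):
        within = (d <= t + 1e-9)
        np.fill_diagonal(within, False)
        if edge_correction:
            n_full = int((od <= t + 1e-9).sum())
            n_in = (d <= t + 1e-9).sum(axis=1)  # includes self
            e = n_full / n_in
        else:
            e = np.ones(n)
        out[k] = area_nm2 * np.einsum("i,ij,j->", w * e, within, w) / total ** 2
    return out


def build_csr_null(field: IntensityField, grid: RadiusGrid,
                   null: CsrNull | None = None,
                   edge_correction: bool = True,
                   engine: RipleyEngine | None = None) -> CsrNull:
    """Build the within-mask intensity-permutation CSR null.

    Each simulation permutes the masked pixel intensities uniformly at
    random (the intensity multiset is preserved exactly), recomputes
    K(r), and the per-radius mean, SD (ddof=1) and the requested
    quantiles over simulations are stored on the returned spec.
    """
    null = null or CsrNull()
    eng = engine or _engine_for(field, grid, edge_correction)
    vals = field.values[field.mask]
    if np.count_nonzero(vals) < 2:
        raise InvalidParameterError(
            "degenerate field: needs weight in at least two pixels")
    rng = np.random.default_rng(null.seed)
    area_nm2 = eng.n_mask * field.pixel_size_nm ** 2
    total2 = vals.sum() ** 2
    ks = np.empty((null.n_simulations, eng.nr))
    w = np.zeros(field.values.shape)
    for s in range(null.n_simulations):
        w[field.mask] = rng.permutation(vals)
        ks[s] = area_nm2 * eng.pair_sums(w) / total2
    null.radii_nm = grid.radii_nm.copy()
    null.mean = ks.mean(axis=0)
    null.sd = ks.std(axis=0, ddof=1)
    null.q_low = np.quantile(ks, null.quantile_low, axis=0)
    null.q_high = np.quantile(ks, null.quantile_high, axis=0)
    return null


def normalize_k(k_raw: np.ndarray, null: CsrNull) -> np.ndarray:
    """K-tilde(r) = (K(r) - null mean) / null SD."""
    if null.mean is None or null.sd is None:
        raise InvalidParameterError("null has not been built")
    bad = np.nonzero(null.sd == 0)[0]
    if len(bad):
        raise InvalidParameterError(
            f"null SD is zero at radius {null.radii_nm[bad[0]]:.0f} nm")
    return (np.asarray(k_raw) - null.mean) / null.sd


def summarize_k(radii_nm: np.ndarray, k_raw: np.ndarray,
                null: CsrNull) -> KCurve:
    """Normalize, classify per radius, and extract argmax(K-tilde)."""
    k_tilde = normalize_k(k_raw, null)
    env_low = (null.q_low - null.mean) / null.sd
    env_high = (null.q_high - null.mean) / null.sd
    classification = np.where(
        k_tilde > env_high, "clustered",
        np.where(k_tilde < env_low, "dispersed", "random")).astype(object)
    idx = int(np.argmax(k_tilde))  # np.argmax returns the first (smallest-r) tie
    return KCurve(
        radii_nm=np.asarray(radii_nm, dtype=float), k_raw=np.asarray(k_raw),
        k_tilde=k_tilde, env_low=env_low, env_high=env_high,
        classification=classification,
        argmax_radius_nm=float(radii_nm[idx]), argmax_value=float(k_tilde[idx]),
        null=null,
    )


def analyze_field(field: IntensityField, grid: RadiusGrid,
                  n_simulations: int = 200, quantile_low: float = 0.01,
                  quantile_high: float = 0.99, seed: int = 0,
                  edge_correction: bool = True) -> KCurve:
    """Full single-field analysis: K, permutation null, K-tilde, argmax."""
    eng = _engine_for(field, grid, edge_correction)
    k_raw = eng.k(field.values, field.pixel_size_nm)
    null = build_csr_null(
        field, grid,
        CsrNull(n_simulations=n_simulations, quantile_low=quantile_low,
                quantile_high=quantile_high, seed=seed),
        edge_correction=edge_correction, engine=eng)
    curve = summarize_k(grid.radii_nm, k_raw, null)
    curve.meta["edge_correction"] = edge_correction
    return curve


def compare_argmax_groups(groups: dict[str, Any]):
    """Kruskal-Wallis omnibus plus Dunn pairwise tests on argmax values.

    Thin wrapper around :func:`nanolayers.quant.kruskal_dunn`; groups
    must each have n >= 3.
    """
    from nanolayers.quant import kruskal_dunn

    if len(groups) < 2:
        raise InvalidParameterError("need >= 2 groups")
    for label, vals in groups.items():
        if len(vals) < 3:
            raise InvalidParameterError(f"group {label!r} has n < 3")
    return kruskal_dunn(groups)
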