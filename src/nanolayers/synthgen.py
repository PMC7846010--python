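"""Ground-truth synthetic inputs for every analysis stage.

Three generators are provided:

* :func:`simulate_blinking_stack` — a temporal stack of diffraction-limited
  frames of stochastically blinking point emitters, the raw material for
  SRRF reconstruction.
* :func:`simulate_membrane_pair` — two fluorescence channels draped on a
  deformed membrane centerline with a known signed normal offset between
  the layers, the ground truth for carpet alignment and inter-layer
  distance estimation.
* :func:`simulate_point_field` — rasterized realizations of CSR, Thomas
  (clustered) and Matérn-II hard-core (dispersed) point processes, the
  ground truth for the Ripley statistics.

Every generator is a pure function of its parameters and seed, and every
output embeds its generating parameters in ``provenance``/``metadata``.

The point-spread function is an isotropic 2-D Gaussian integrated exactly
over pixel areas (separable error-function profile), so a fully contained
emitter deposits exactly ``brightness`` expected photons in the image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.interpolate import CubicSpline
from scipy.special import erf

from nanolayers.containers import (
    GeometryError,
    ImageStack,
    InvalidParameterError,
    SuperResImage,
)

__all__ = [
    "EmitterField",
    "MembraneModel",
    "PointProcessSpec",
    "NoiseSpec",
    "simulate_blinking_stack",
    "simulate_membrane_pair",
    "simulate_point_field",
]


@dataclass
class EmitterField:
    """Point emitters inside a rectangular window.

    positions : ndarray (N, 2)
        Continuous (x, y) coordinates in nm.
    brightness : float
        Expected photons per frame while the emitter is on.
    on_probability : float
        Probability of being in the on state in any given frame.  With
        ``on_dwell_frames`` unset the per-frame states are independent
        Bernoulli draws.
    window_nm : (float, float)
        Window extent (width_x, height_y) in nm; all positions must lie
        inside.
    on_dwell_frames : float, optional
        Mean duration (frames) of an on period.  When set, the on/off
        state follows a two-state Markov (telegraph) process with this
        mean on-dwell and stationary probability ``on_probability`` —
        the realistic regime for fluorophore photophysics, where on
        states persist across consecutive frames and second-order
        temporal cumulants at lag 1 are informative.
    """

    positions: np.ndarray
    brightness: float
    on_probability: float
    window_nm: tuple[float, float]
    on_dwell_frames: float | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        wx, wy = self.window_nm
        if not (self.brightness > 0):
            raise InvalidParameterError("brightness must be > 0")
        if not (0.0 <= self.on_probability <= 1.0):
            raise InvalidParameterError("on_probability must be in [0, 1]")
        x, y = self.positions[:, 0], self.positions[:, 1]
        if np.any((x < 0) | (x > wx) | (y < 0) | (y > wy)):
            raise InvalidParameterError("all emitter positions must lie inside the window")


@dataclass
class MembraneModel:
    """A single membrane stripe carrying two fluorescent layers.

    The centerline is a single-valued smooth curve y0(x) across the
    window; each layer sits at a signed offset along the local curve
    normal (negative = toward the cytoplasm, i.e. smaller y).  Layer 0
    is the reference layer.
    """

    window_nm: tuple[float, float]
    layer_offsets_nm: tuple[float, float]
    deformation_amplitude_nm: float = 200.0
    deformation_correlation_length_nm: float = 1000.0
    emitter_density_per_um: float = 50.0
    brightness: float = 100.0
    base_y_nm: float | None = None

    def __post_init__(self) -> None:
        if len(self.layer_offsets_nm) != 2:
            raise InvalidParameterError("exactly two layers are supported")
        if not self.deformation_correlation_length_nm > 0:
            raise InvalidParameterError("deformation_correlation_length must be > 0")
        if self.deformation_amplitude_nm < 0:
            raise InvalidParameterError("deformation_amplitude must be >= 0")
        if self.base_y_nm is None:
            self.base_y_nm = self.window_nm[1] / 2.0


@dataclass
class PointProcessSpec:
    """Specification of a planar point process in a rectangular window.

    ``kind`` is one of ``csr`` (homogeneous Poisson), ``thomas``
    (Poisson parents with Gaussian-scattered offspring) or ``hardcore``
    (Matérn-II dependent thinning).  ``intensity`` is the point density
    in points/µm² for ``csr`` and ``hardcore`` (proposal density before
    thinning) and the *parent* density for ``thomas``.
    """

    kind: str
    window_um: tuple[float, float]
    intensity_per_um2: float
    cluster_sigma_nm: float | None = None
    offspring_mean: float | None = None
    inhibition_radius_nm: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("csr", "thomas", "hardcore"):
            raise InvalidParameterError(f"unknown point process kind {self.kind!r}")
        if not self.intensity_per_um2 > 0:
            raise InvalidParameterError("intensity must be > 0")
        if self.kind == "thomas":
            if not (self.cluster_sigma_nm and self.cluster_sigma_nm > 0):
                raise InvalidParameterError("thomas requires cluster_sigma > 0")
            if not (self.offspring_mean and self.offspring_mean > 0):
                raise InvalidParameterError("thomas requires offspring_mean > 0")
        if self.kind == "hardcore":
            if not (self.inhibition_radius_nm and self.inhibition_radius_nm > 0):
                raise InvalidParameterError("hardcore requires inhibition_radius > 0")


@dataclass
class NoiseSpec:
    """Detection noise: Poisson shot noise then additive Gaussian read noise."""

    poisson: bool = True
    read_sigma: float = 1.0
    background: float = 0.0  # expected photons per pixel per frame

    def apply(self, expected: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = expected + self.background
        if self.poisson:
            out = rng.poisson(np.clip(out, 0, None)).astype(float)
        if self.read_sigma > 0:
            out = out + rng.normal(0.0, self.read_sigma, size=out.shape)
        return out


NO_NOISE = NoiseSpec(poisson=False, read_sigma=0.0, background=0.0)


def _pixel_profiles(coords_nm: np.ndarray, n_pix: int, pixel_size_nm: float,
                    psf_sigma_nm: float) -> np.ndarray:
    """Per-emitter 1-D pixel-integrated Gaussian profiles, shape (N, n_pix).

    Pixel ``i`` covers ``[i, i+1) * pixel_size``; each row integrates to 1
    when the PSF lies fully inside the axis range.
    """
    edges = np.arange(n_pix + 1) * pixel_size_nm
    z = (edges[None, :] - coords_nm[:, None]) / (np.sqrt(2.0) * psf_sigma_nm)
    cdf = 0.5 * (1.0 + erf(z))
    return np.diff(cdf, axis=1)


def _render_emitters(positions_nm: np.ndarray, weights: np.ndarray,
                     shape: tuple[int, int], pixel_size_nm: float,
                     psf_sigma_nm: float) -> np.ndarray:
    """Expected photon image of emitters with per-emitter total weights."""
    h, w = shape
    img = np.zeros((h, w))
    if len(positions_nm) == 0:
        return img
    if psf_sigma_nm == 0:
        # delta rasterization: each point deposits its weight in one pixel
        img, _, _ = np.histogram2d(
            positions_nm[:, 1], positions_nm[:, 0],
            bins=(h, w), range=((0, h * pixel_size_nm), (0, w * pixel_size_nm)),
            weights=weights)
        return img
    px = _pixel_profiles(positions_nm[:, 0], w, pixel_size_nm, psf_sigma_nm)
    py = _pixel_profiles(positions_nm[:, 1], h, pixel_size_nm, psf_sigma_nm)
    return np.einsum("n,nh,nw->hw", weights, py, px, optimize=True)


def _on_states(rng: np.random.Generator, n: int, n_frames: int,
               p_on: float, dwell: float | None) -> np.ndarray:
    """Per-frame on-state matrix (n_frames, n): iid Bernoulli or telegraph."""
    if dwell is None:
        return rng.random((n_frames, n)) < p_on
    if p_on in (0.0, 1.0):
        return np.broadcast_to(np.full(n, bool(p_on)), (n_frames, n)).copy()
    q_off = 1.0 / dwell                      # P(on -> off)
    q_on = p_on / (dwell * (1.0 - p_on))     # P(off -> on), stationary p_on
    if q_off > 1.0 or q_on > 1.0:
        raise InvalidParameterError(
            "on_dwell_frames too short for the requested on_probability")
    states = np.empty((n_frames, n), dtype=bool)
    states[0] = rng.random(n) < p_on
    for t in range(1, n_frames):
        u = rng.random(n)
        states[t] = np.where(states[t - 1], u >= q_off, u < q_on)
    return states


def simulate_blinking_stack(field: EmitterField, n_frames: int,
                            psf_sigma_nm: float, pixel_size_nm: float,
                            noise: NoiseSpec = NO_NOISE, seed: int = 0,
                            bleach_tau_frames: float | None = None) -> ImageStack:
    """Simulate a temporal stack of diffraction-limited frames.

    Each frame is the pixel-integrated sum of the PSFs of the emitters
    that are in the on state that frame, plus detection noise.  With
    ``bleach_tau_frames`` set, the on-probability decays exponentially
    over frames (photobleaching); it is off by default.
    """
    if n_frames < 2:
        raise InvalidParameterError("n_frames must be >= 2")
    if not psf_sigma_nm > 0 or not pixel_size_nm > 0:
        raise InvalidParameterError("psf_sigma and pixel_size must be > 0")
    if psf_sigma_nm < pixel_size_nm / 2:
        raise InvalidParameterError("psf_sigma must be >= pixel_size/2 (Nyquist)")

    wx, wy = field.window_nm
    shape = (int(round(wy / pixel_size_nm)), int(round(wx / pixel_size_nm)))
    rng = np.random.default_rng(seed)

    n = len(field.positions)
    px = _pixel_profiles(field.positions[:, 0], shape[1], pixel_size_nm, psf_sigma_nm)
    py = _pixel_profiles(field.positions[:, 1], shape[0], pixel_size_nm, psf_sigma_nm)

    states = _on_states(rng, n, n_frames, field.on_probability,
                        field.on_dwell_frames)
    if bleach_tau_frames is not None:
        # absorbing photobleaching: per-frame survival probability
        survive = rng.random((n_frames, n)) < np.exp(-1.0 / bleach_tau_frames)
        survive[0] = True
        states &= np.cumprod(survive, axis=0).astype(bool)

    frames = np.empty((n_frames, *shape))
    for t in range(n_frames):
        on = states[t]
        if on.any():
            expected = field.brightness * np.einsum(
                "nh,nw->hw", py[on], px[on], optimize=True)
        else:
            expected = np.zeros(shape)
        frames[t] = noise.apply(expected, rng)

    return ImageStack(
        frames=frames, pixel_size_nm=pixel_size_nm,
        metadata={
            "ground_truth": {
                "positions_nm": field.positions.tolist(),
                "brightness": field.brightness,
                "on_probability": field.on_probability,
                "psf_sigma_nm": psf_sigma_nm,
                "seed": seed,
            }
        },
    )


def sample_centerline(model: MembraneModel, x_nm: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Sample the deformed membrane centerline y0(x) at the given x.

    The deformation is a zero-mean Gaussian process with a squared
    exponential covariance (standard deviation =
    ``deformation_amplitude_nm``, length scale =
    ``deformation_correlation_length_nm``), the simplest smooth model
    that produces the stretching and folding seen at apical membranes.
    """
    if model.deformation_amplitude_nm == 0:
        return np.full_like(x_nm, float(model.base_y_nm))
    ell = model.deformation_correlation_length_nm
    # sample on a coarse grid (<= ell/4 spacing) and spline-interpolate
    step = max(ell / 4.0, 1.0)
    xg = np.arange(x_nm.min() - 2 * step, x_nm.max() + 2 * step + step, step)
    d = xg[:, None] - xg[None, :]
    cov = model.deformation_amplitude_nm ** 2 * np.exp(-0.5 * (d / ell) ** 2)
    cov[np.diag_indices_from(cov)] += 1e-8 * model.deformation_amplitude_nm ** 2
    yg = np.linalg.cholesky(cov) @ rng.standard_normal(len(xg))
    return float(model.base_y_nm) + CubicSpline(xg, yg)(x_nm)


def simulate_membrane_pair(model: MembraneModel, psf_sigma_nm: float,
                           pixel_size_nm: float, seed: int = 0,
                           noise: NoiseSpec = NO_NOISE,
                           positions_nm: np.ndarray | None = None,
                           ) -> tuple[SuperResImage, SuperResImage]:
    """Render the two fluorescence layers of a deformed membrane.

    Returns one :class:`SuperResImage` per layer; index 0 is the
    reference layer.  Both images share geometry and pixel size and
    carry the ground-truth offsets and centerline in ``provenance``.

    With ``positions_nm`` given (shape (N,) of x positions), the same
    lateral emitter positions are used for both layers; otherwise each
    layer draws an independent Poisson set of emitters along the
    centerline.
    """
    if not psf_sigma_nm > 0 or not pixel_size_nm > 0:
        raise InvalidParameterError("psf_sigma and pixel_size must be > 0")
    wx, wy = model.window_nm
    shape = (int(round(wy / pixel_size_nm)), int(round(wx / pixel_size_nm)))
    rng = np.random.default_rng(seed)

    xc = (np.arange(shape[1]) + 0.5) * pixel_size_nm
    y_center = sample_centerline(model, xc, rng)
    spline = CubicSpline(xc, y_center)

    images = []
    for layer, offset in enumerate(model.layer_offsets_nm):
        if positions_nm is not None:
            x = np.asarray(positions_nm, dtype=float)
        else:
            n = rng.poisson(model.emitter_density_per_um * wx / 1000.0)
            x = rng.uniform(0.0, wx, size=n)
        y0 = spline(x)
        slope = spline(x, 1)
        # unit normal pointing toward +y (lumen)
        norm = np.sqrt(1.0 + slope ** 2)
        pos = np.column_stack([x - offset * slope / norm, y0 + offset / norm])
        if np.any((pos[:, 1] < 0) | (pos[:, 1] > wy)):
            raise GeometryError(
                "deformed membrane plus layer offset does not fit inside the window"
            )
        expected = _render_emitters(pos, np.full(len(pos), model.brightness),
                                    shape, pixel_size_nm, psf_sigma_nm)
        values = np.clip(noise.apply(expected, rng), 0.0, None)
        images.append(SuperResImage(
            values=values, pixel_size_nm=pixel_size_nm,
            provenance={
                "ground_truth": {
                    "layer": layer,
                    "layer_offsets_nm": list(model.layer_offsets_nm),
                    "reference_layer": 0,
                    "centerline_x_nm": xc.tolist(),
                    "centerline_y_nm": y_center.tolist(),
                    "deformation_amplitude_nm": model.deformation_amplitude_nm,
                    "deformation_correlation_length_nm":
                        model.deformation_correlation_length_nm,
                    "psf_sigma_nm": psf_sigma_nm,
                    "seed": seed,
                }
            },
        ))
    return images[0], images[1]


def _realize_points(spec: PointProcessSpec, rng: np.random.Generator) -> np.ndarray:
    wx_nm, wy_nm = spec.window_um[0] * 1000.0, spec.window_um[1] * 1000.0
    area_um2 = spec.window_um[0] * spec.window_um[1]

    if spec.kind == "csr":
        n = rng.poisson(spec.intensity_per_um2 * area_um2)
        return np.column_stack([rng.uniform(0, wx_nm, n), rng.uniform(0, wy_nm, n)])

    if spec.kind == "thomas":
        sigma = float(spec.cluster_sigma_nm)
        pad = 4.0 * sigma
        area_pad = (wx_nm + 2 * pad) * (wy_nm + 2 * pad) / 1e6
        n_par = rng.poisson(spec.intensity_per_um2 * area_pad)
        parents = np.column_stack([
            rng.uniform(-pad, wx_nm + pad, n_par),
            rng.uniform(-pad, wy_nm + pad, n_par),
        ])
        counts = rng.poisson(float(spec.offspring_mean), size=n_par)
        pts = np.repeat(parents, counts, axis=0)
        pts = pts + rng.normal(0.0, sigma, size=pts.shape)
        keep = ((pts[:, 0] >= 0) & (pts[:, 0] <= wx_nm)
                & (pts[:, 1] >= 0) & (pts[:, 1] <= wy_nm))
        return pts[keep]

    # Matérn-II: Poisson proposals with uniform marks; a point survives if
    # no other proposal with a smaller mark lies within the inhibition radius.
    h = float(spec.inhibition_radius_nm)
    n = rng.poisson(spec.intensity_per_um2 * area_um2)
    pts = np.column_stack([rng.uniform(0, wx_nm, n), rng.uniform(0, wy_nm, n)])
    marks = rng.random(n)
    if n == 0:
        return pts
    tree = cKDTree(pts)
    keep = np.ones(n, bool)
    for i, j in tree.query_pairs(h):
        if marks[i] < marks[j]:
            keep[j] = False
        else:
            keep[i] = False
    return pts[keep]


def simulate_point_field(spec: PointProcessSpec, psf_sigma_nm: float,
                         pixel_size_nm: float, brightness: float = 100.0,
                         noise: NoiseSpec = NO_NOISE) -> SuperResImage:
    """Rasterize a realization of the specified point process.

    Each realized point is rendered as a pixel-integrated Gaussian spot
    of total expected intensity ``brightness``; with ``psf_sigma_nm=0``
    points are delta-rasterized (each deposits its full weight in the
    pixel containing it), giving a field whose pixel weights carry no
    instrumental correlation — the appropriate input when calibrating
    against the pixel-permutation CSR null.  The realized point list is
    kept in ``provenance['ground_truth']['points_nm']``.
    """
    if psf_sigma_nm < 0 or not pixel_size_nm > 0:
        raise InvalidParameterError("psf_sigma and pixel_size must be > 0")
    area_um2 = spec.window_um[0] * spec.window_um[1]
    expected_n = spec.intensity_per_um2 * area_um2
    if spec.kind == "thomas":
        expected_n *= float(spec.offspring_mean)
    if expected_n < 10:
        warnings.warn(
            f"expected point count {expected_n:.1f} < 10: spatial statistics "
            "on this field will be unreliable", stacklevel=2)

    rng = np.random.default_rng(spec.seed)
    pts = _realize_points(spec, rng)
    shape = (int(round(spec.window_um[1] * 1000.0 / pixel_size_nm)),
             int(round(spec.window_um[0] * 1000.0 / pixel_size_nm)))
    expected = _render_emitters(pts, np.full(len(pts), brightness),
                                shape, pixel_size_nm, psf_sigma_nm)
    values = np.clip(noise.apply(expected, rng), 0.0, None)
    return SuperResImage(
        values=values, pixel_size_nm=pixel_size_nm,
        provenance={
            "ground_truth": {
                "kind": spec.kind,
                "points_nm": pts.tolist(),
                "intensity_per_um2": spec.intensity_per_um2,
                "cluster_sigma_nm": spec.cluster_sigma_nm,
                "offspring_mean": spec.offspring_mean,
                "inhibition_radius_nm": spec.inhibition_radius_nm,
                "psf_sigma_nm": psf_sigma_nm,
                "seed": spec.seed,
            }
        },
    )
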