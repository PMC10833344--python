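"""Desk-scale kinematic diffraction simulator with automatic labels.

Renders still (or narrow-rotation) macromolecular diffraction images under
kinematic (single-scattering) theory and labels each image from the ground
truth that generated it, so that large training sets need no hand
annotation.  Controllable knobs: overall B factor (via the resolution
trend), 1-3 overlapping lattices with a chosen misorientation spread,
mosaic spread, radially symmetric background with optional ice rings,
beamstop/bad-pixel/hot-pixel masks, Poisson photon noise and Gaussian
read noise.

The physics, in brief: reciprocal-lattice points ``q = U B h`` (U the
crystal orientation, B the reciprocal cell basis, h the Miller index) are
excited when they lie close to the Ewald sphere of radius ``1/lambda``;
the excitation error ``eps`` is the distance from the sphere surface.
Stills weight each reflection by a Gaussian envelope
``exp(-eps^2 / 2 sigma_E^2)`` whose width collects mosaic spread, beam
bandwidth and a crystal-size floor; rotation frames accept at full weight
any reflection swept through the sphere within the rotation width.
Expected spot intensity is ``flux_scale * F^2 * exp(-B / 2 d^2)`` with
``F^2`` drawn per reflection from the exponential (random-structure)
intensity distribution.  Spots are isotropic 2-D Gaussians on the
detector; every lattice's contribution is summed before background and
noise.

Determinism contract: ``(config, seed)`` fully determines every image
byte — scenes record their own noise seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .condition import MASK_SENTINEL
from .geometry import (GeometryContext, make_context, pixel_radius_map,
                       pixel_resolution_map, resolution_at_radius)
from .trend import DEFAULT_TREND, TrendModel, b_from_resolution, resolution_from_b

__all__ = [
    "SimulationConfig", "CrystalModel", "LatticeEnsemble", "SimScene",
    "LabeledImage", "EmptyPatternWarning", "sample_scene", "render_spots",
    "add_background", "apply_detector", "make_labeled_example",
    "generate_examples", "build_training_set", "count_bragg_peaks",
    "reflection_intensity",
]


class EmptyPatternWarning(UserWarning):
    """No reciprocal-lattice point reaches the detector: background only."""


@dataclass(frozen=True)
class SimulationConfig:
    """All sampled quantities of the generator, with their distributions.

    Defaults are the training conditions of the shipped models: distances
    uniform in 200-300 mm, wavelength 0.9795 A, lattice-count mixture
    50/25/25, misorientation spreads drawn from {0.1, 1, 10} degrees,
    mosaic spread below 0.01 degrees, background scales spanning
    0.01-1.25 (log-uniform).  Target resolutions are drawn uniformly over
    ``d_range`` and converted to B factors through the trend.
    """

    task: str = "resolution"                 # resolution | overlap
    preset: str = "toy"
    distance_range_mm: tuple[float, float] = (200.0, 300.0)
    wavelength_A: float = 0.9795
    beam_center_jitter_px: float = 3.0
    beamstop_range_mm: tuple[float, float] = (0.5, 2.0)
    d_range_A: tuple[float, float] = (1.5, 4.5)
    lattice_probs: tuple[float, float, float] = (0.5, 0.25, 0.25)
    misorientation_sigmas_deg: tuple[float, ...] = (0.1, 1.0, 10.0)
    mosaic_deg: float = 0.005
    cell: tuple[float, float, float, float, float, float] = (50.0, 50.0, 50.0,
                                                             90.0, 90.0, 90.0)
    background_range: tuple[float, float] = (0.01, 1.25)
    ice_rings: bool = False
    hot_pixel_range: tuple[int, int] = (0, 50)
    bad_region_range: tuple[int, int] = (0, 3)
    bad_region_max_px: int = 20
    rotation_width_deg: float = 0.0
    spot_sigma_px: float = 1.2
    excitation_sigma_floor: float = 2e-3     # A^-1, crystal-size broadening
    bandwidth_frac: float = 3e-3             # delta(lambda)/lambda
    amplitude_scale: float = 1000.0          # photons, strongest reflection
    read_noise: float = 1.0                  # counts rms
    trend: TrendModel = field(default_factory=TrendModel)

    def __post_init__(self) -> None:
        if self.task not in ("resolution", "overlap"):
            raise ValueError("task must be 'resolution' or 'overlap'")
        p = np.asarray(self.lattice_probs, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("lattice_probs must be 3 non-negative values summing to 1")
        lo, hi = self.distance_range_mm
        if not 0 < lo <= hi:
            raise ValueError("invalid distance range")
        d_lo, d_hi = self.d_range_A
        if not 0 < d_lo < d_hi:
            raise ValueError("invalid resolution range")
        if not all(s > 0 for s in self.misorientation_sigmas_deg):
            raise ValueError("misorientation spreads must be positive")
        if self.mosaic_deg < 0 or self.rotation_width_deg < 0:
            raise ValueError("mosaic and rotation width must be >= 0")


@dataclass
class CrystalModel:
    """One lattice: shared unit cell, own orientation, disorder and scale."""

    cell: tuple[float, float, float, float, float, float]
    orientation: np.ndarray                  # 3x3 rotation, lab frame
    mosaic_deg: float
    b_factor: float
    amplitude_scale: float

    def __post_init__(self) -> None:
        a, b, c, al, be, ga = self.cell
        if min(a, b, c) <= 0 or not all(0 < x < 180 for x in (al, be, ga)):
            raise ValueError("invalid unit cell")
        if self.mosaic_deg < 0 or self.b_factor < 0:
            raise ValueError("mosaic spread and B factor must be >= 0")


@dataclass
class LatticeEnsemble:
    """1-3 co-illuminated lattices drawn around a nominal orientation."""

    n_lattices: int
    misorientation_sigma_deg: float
    crystals: list[CrystalModel]

    def __post_init__(self) -> None:
        if self.n_lattices not in (1, 2, 3):
            raise ValueError("n_lattices must be 1, 2 or 3")
        if len(self.crystals) != self.n_lattices:
            raise ValueError("ensemble must hold n_lattices crystals")


@dataclass
class SimScene:
    """A fully specified simulated exposure (reproducible from its record)."""

    geometry: GeometryContext
    ensemble: LatticeEnsemble
    background_scale: float
    rotation_width_deg: float
    ice_rings: bool
    hot_pixels: np.ndarray                   # (n, 2) (slow, fast) indices
    bad_regions: list[tuple[int, int, int, int]]   # (s0, s1, f0, f1)
    read_noise: float
    noise_seed: int
    d_label_A: float
    spot_sigma_px: float = 1.2
    excitation_sigma_floor: float = 2e-3
    bandwidth_frac: float = 3e-3

    def to_json(self) -> str:
        """Canonical JSON record of the scene (byte-identical per seed)."""
        payload = {
            "geometry": self.geometry.to_config(),
            "background_scale": self.background_scale,
            "rotation_width_deg": self.rotation_width_deg,
            "ice_rings": self.ice_rings,
            "hot_pixels": self.hot_pixels.tolist(),
            "bad_regions": [list(r) for r in self.bad_regions],
            "read_noise": self.read_noise,
            "noise_seed": self.noise_seed,
            "d_label_A": self.d_label_A,
            "spot_sigma_px": self.spot_sigma_px,
            "excitation_sigma_floor": self.excitation_sigma_floor,
            "bandwidth_frac": self.bandwidth_frac,
            "ensemble": {
                "n_lattices": self.ensemble.n_lattices,
                "misorientation_sigma_deg": self.ensemble.misorientation_sigma_deg,
                "crystals": [
                    {"cell": list(c.cell),
                     "orientation": np.round(c.orientation, 12).tolist(),
                     "mosaic_deg": c.mosaic_deg,
                     "b_factor": c.b_factor,
                     "amplitude_scale": c.amplitude_scale}
                    for c in self.ensemble.crystals],
            },
        }
        return json.dumps(payload, sort_keys=True)


@dataclass
class LabeledImage:
    """Rendered detector counts plus ground-truth labels."""

    pixels: np.ndarray                       # int32 counts, -1 mask sentinel
    inverse_resolution: float                # 1/d, A^-1
    n_lattices: int
    is_overlapped: bool
    b_factor: float
    scene: SimScene


# -- crystallographic helpers ---------------------------------------------

def reciprocal_basis(cell) -> np.ndarray:
    """Columns are the reciprocal basis vectors a*, b*, c* (A^-1)."""
    a, b, c, al, be, ga = cell
    al, be, ga = np.radians([al, be, ga])
    ca, cb, cg, sg = np.cos(al), np.cos(be), np.cos(ga), np.sin(ga)
    v = np.sqrt(1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg)
    A = np.array([
        [a, b * cg, c * cb],
        [0, b * sg, c * (ca - cb * cg) / sg],
        [0, 0, c * v / sg],
    ])
    return np.linalg.inv(A).T


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def axis_angle_rotation(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)


def reflection_intensity(f2, b_factor, d_A, amplitude_scale=1.0):
    """Expected photons of a reflection: ``amplitude * F^2 * exp(-B / 2 d^2)``."""
    d = np.asarray(d_A, dtype=float)
    return amplitude_scale * np.asarray(f2, dtype=float) * np.exp(
        -np.asarray(b_factor, dtype=float) / (2.0 * d * d))


# hkl grids keyed by (cell rounded, qmax bucket); built once, reused per scene
_HKL_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _hkl_grid(cell, q_max: float):
    key = (tuple(np.round(cell, 6)), float(np.ceil(q_max / 0.05) * 0.05))
    hit = _HKL_CACHE.get(key)
    if hit is not None:
        return hit
    bmat = reciprocal_basis(cell)
    q_bucket = key[1]
    # box bounds from the direct cell lengths (safe overestimate)
    nmax = [int(np.ceil(q_bucket * L)) + 1 for L in cell[:3]]
    h = np.arange(-nmax[0], nmax[0] + 1)
    k = np.arange(-nmax[1], nmax[1] + 1)
    l = np.arange(-nmax[2], nmax[2] + 1)
    hkl = np.stack(np.meshgrid(h, k, l, indexing="ij"), axis=-1).reshape(-1, 3)
    q0 = hkl @ bmat.T
    qn = np.linalg.norm(q0, axis=1)
    keep = (qn <= q_bucket) & (qn > 1e-9)
    out = (np.ascontiguousarray(q0[keep]), qn[keep])
    _HKL_CACHE[key] = out
    return out


# -- scene sampling -------------------------------------------------------

def sample_scene(config: SimulationConfig, rng: np.random.Generator) -> SimScene:
    """Draw one fully specified scene from the configured distributions."""
    distance = rng.uniform(*config.distance_range_mm)
    ctx = make_context(config.preset, distance, wavelength_A=config.wavelength_A)
    det = ctx.detector
    jitter = rng.normal(0.0, config.beam_center_jitter_px, size=2)
    center = (ctx.beam.center_fast_px + jitter[0],
              ctx.beam.center_slow_px + jitter[1])
    beamstop = rng.uniform(*config.beamstop_range_mm)
    ctx = make_context(config.preset, distance, wavelength_A=config.wavelength_A,
                       beam_center=center, beamstop_mm=beamstop)

    if config.task == "resolution":
        n_lat = 1
    else:
        n_lat = int(rng.choice((1, 2, 3), p=config.lattice_probs))
    sigma_mis = float(rng.choice(config.misorientation_sigmas_deg))
    d_target = rng.uniform(*config.d_range_A)
    b_factor = float(b_from_resolution(d_target, config.trend))

    u0 = random_rotation(rng)
    crystals = []
    for i in range(n_lat):
        if i == 0:
            u = u0
        else:
            angle = np.radians(rng.normal(0.0, sigma_mis))
            u = axis_angle_rotation(rng.normal(size=3), angle) @ u0
        crystals.append(CrystalModel(cell=config.cell, orientation=u,
                                     mosaic_deg=config.mosaic_deg,
                                     b_factor=b_factor,
                                     amplitude_scale=config.amplitude_scale))
    ensemble = LatticeEnsemble(n_lat, sigma_mis, crystals)

    n_hot = int(rng.integers(config.hot_pixel_range[0],
                             config.hot_pixel_range[1] + 1))
    hot = np.column_stack([rng.integers(0, det.n_slow, n_hot),
                           rng.integers(0, det.n_fast, n_hot)])
    n_bad = int(rng.integers(config.bad_region_range[0],
                             config.bad_region_range[1] + 1))
    bad = []
    for _ in range(n_bad):
        hgt = int(rng.integers(1, config.bad_region_max_px + 1))
        wid = int(rng.integers(1, config.bad_region_max_px + 1))
        s0 = int(rng.integers(0, max(det.n_slow - hgt, 1)))
        f0 = int(rng.integers(0, max(det.n_fast - wid, 1)))
        bad.append((s0, s0 + hgt, f0, f0 + wid))

    background = float(np.exp(rng.uniform(*np.log(config.background_range))))
    noise_seed = int(rng.integers(0, 2 ** 31 - 1))
    return SimScene(geometry=ctx, ensemble=ensemble,
                    background_scale=background,
                    rotation_width_deg=config.rotation_width_deg,
                    ice_rings=config.ice_rings, hot_pixels=hot,
                    bad_regions=bad, read_noise=config.read_noise,
                    noise_seed=noise_seed, d_label_A=d_target,
                    spot_sigma_px=config.spot_sigma_px,
                    excitation_sigma_floor=config.excitation_sigma_floor,
                    bandwidth_frac=config.bandwidth_frac)


# -- rendering ------------------------------------------------------------

def _corner_qmax(ctx: GeometryContext) -> float:
    det, beam = ctx.detector, ctx.beam
    corners_f = np.array([0, det.n_fast - 1], dtype=float)
    corners_s = np.array([0, det.n_slow - 1], dtype=float)
    rmax = 0.0
    for f in corners_f:
        for s in corners_s:
            r = np.hypot((f - beam.center_fast_px) * det.pixel_mm,
                         (s - beam.center_slow_px) * det.pixel_mm)
            rmax = max(rmax, float(r))
    d_min = resolution_at_radius(rmax, ctx.distance_mm, beam.wavelength_A)
    return 1.0 / d_min


def render_spots(scene: SimScene, return_spots: bool = False,
                 spot_sigma_px: float | None = None):
    """Photon-expectation image of all Bragg spots (no background, no noise).

    With ``return_spots=True`` also returns a per-reflection table of
    ``(d_A, intensity_photons)`` for the reflections that landed on the
    detector — handy for intensity-statistics checks without spot-profile
    or noise corrections.
    """
    ctx = scene.geometry
    det, beam = ctx.detector, ctx.beam
    lam = beam.wavelength_A
    k = 1.0 / lam
    if spot_sigma_px is None:
        spot_sigma_px = scene.spot_sigma_px
    image = np.zeros((det.n_slow, det.n_fast), dtype=np.float64)
    q_max = _corner_qmax(ctx)
    cell = scene.ensemble.crystals[0].cell
    q0, _ = _hkl_grid(cell, q_max)
    if q0.shape[0] == 0:
        warnings.warn("no reciprocal-lattice point within the detector range",
                      EmptyPatternWarning, stacklevel=2)
        return (image, np.empty((0, 2))) if return_spots else image
    # structure-factor draws are a property of the scene, not of geometry
    f2_rng = np.random.default_rng(scene.noise_seed ^ 0x5EED)

    spot_d, spot_i = [], []
    for crystal in scene.ensemble.crystals:
        f2_all = f2_rng.exponential(1.0, size=q0.shape[0])
        q = q0 @ crystal.orientation.T
        qn = np.linalg.norm(q, axis=1)
        mosaic_rad = np.radians(max(crystal.mosaic_deg, 0.0))
        sigma_e = scene.excitation_sigma_floor + qn * (mosaic_rad + scene.bandwidth_frac)
        sigma_e = np.maximum(sigma_e, 1e-6)
        eps = np.sqrt(q[:, 0] ** 2 + q[:, 1] ** 2 + (q[:, 2] + k) ** 2) - k
        if scene.rotation_width_deg > 0:
            half = np.radians(scene.rotation_width_deg) / 2.0
            rot = axis_angle_rotation(np.array([1.0, 0.0, 0.0]), half)
            q_a = q @ rot.T
            q_b = q @ rot
            eps_a = np.sqrt(q_a[:, 0] ** 2 + q_a[:, 1] ** 2 + (q_a[:, 2] + k) ** 2) - k
            eps_b = np.sqrt(q_b[:, 0] ** 2 + q_b[:, 1] ** 2 + (q_b[:, 2] + k) ** 2) - k
            swept = np.sign(eps_a) != np.sign(eps_b)
            w = np.where(swept, 1.0,
                         np.exp(-np.minimum(eps_a ** 2, eps_b ** 2) / (2 * sigma_e ** 2)))
        else:
            w = np.exp(-eps ** 2 / (2 * sigma_e ** 2))
        keep = w > 1e-3
        if not np.any(keep):
            continue
        qk = q[keep]
        v = qk + np.array([0.0, 0.0, k])
        vn = np.linalg.norm(v, axis=1)
        vhat = v / vn[:, None]
        fwd = vhat[:, 2] > 0.05
        qk, vhat, wk = qk[fwd], vhat[fwd], w[keep][fwd]
        f2 = f2_all[keep][fwd]
        d = 1.0 / np.linalg.norm(qk, axis=1)
        t = ctx.distance_mm / vhat[:, 2]
        pf = beam.center_fast_px + vhat[:, 0] * t / det.pixel_mm
        ps = beam.center_slow_px + vhat[:, 1] * t / det.pixel_mm
        margin = 3 * spot_sigma_px + 1
        on = ((pf > -margin) & (pf < det.n_fast + margin)
              & (ps > -margin) & (ps < det.n_slow + margin))
        if not np.any(on):
            continue
        pf, ps, d = pf[on], ps[on], d[on]
        inten = reflection_intensity(f2[on], crystal.b_factor, d,
                                     crystal.amplitude_scale) * wk[on]
        _stamp_gaussians(image, ps, pf, inten, spot_sigma_px)
        spot_d.append(d)
        spot_i.append(inten)
    if return_spots:
        if spot_d:
            table = np.column_stack([np.concatenate(spot_d),
                                     np.concatenate(spot_i)])
        else:
            table = np.empty((0, 2))
        return image, table
    return image


def _stamp_gaussians(image, ps, pf, intensity, sigma):
    """Accumulate normalized 2-D Gaussian spots (separable kernels)."""
    r = int(np.ceil(3 * sigma))
    offs = np.arange(-r, r + 1)
    ic = np.rint(ps).astype(int)
    jc = np.rint(pf).astype(int)
    gy = np.exp(-((ic[:, None] + offs[None, :] - ps[:, None]) ** 2) / (2 * sigma ** 2))
    gx = np.exp(-((jc[:, None] + offs[None, :] - pf[:, None]) ** 2) / (2 * sigma ** 2))
    norm = gy.sum(axis=1) * gx.sum(axis=1)
    vals = (intensity / norm)[:, None, None] * (gy[:, :, None] * gx[:, None, :])
    ii = (ic[:, None] + offs[None, :])[:, :, None]
    jj = (jc[:, None] + offs[None, :])[:, None, :]
    ii = np.broadcast_to(ii, vals.shape)
    jj = np.broadcast_to(jj, vals.shape)
    ok = (ii >= 0) & (ii < image.shape[0]) & (jj >= 0) & (jj < image.shape[1])
    np.add.at(image, (ii[ok], jj[ok]), vals[ok])


# -- background and detector ----------------------------------------------

#: background profile constants (photons per pixel at background scale 1):
#: a low-angle falloff plus a broad diffuse (water) ring near 3.7 A
_BG_LOW_AMP = 60.0
_BG_LOW_WIDTH = 0.12        # A^-1
_BG_RING_AMP = 25.0
_BG_RING_Q = 1.0 / 3.7      # A^-1
_BG_RING_WIDTH = 0.04       # A^-1
_ICE_RING_D = (3.90, 3.67, 3.44)
_ICE_RING_AMP = 80.0
_ICE_RING_WIDTH = 0.004     # A^-1


def add_background(image: np.ndarray, scene: SimScene) -> np.ndarray:
    """Add the radially symmetric background expectation (photons).

    The profile is a function of the scattering vector magnitude q = 1/d
    only, scaled linearly by the scene's background scale; optional sharp
    ice rings sit at 3.90/3.67/3.44 A.
    """
    d_map = pixel_resolution_map(scene.geometry)
    with np.errstate(divide="ignore"):
        q = np.where(np.isfinite(d_map), 1.0 / d_map, 0.0)
    prof = (_BG_LOW_AMP * np.exp(-(q / _BG_LOW_WIDTH) ** 2)
            + _BG_RING_AMP * np.exp(-(q - _BG_RING_Q) ** 2 / (2 * _BG_RING_WIDTH ** 2)))
    if scene.ice_rings:
        for d_ring in _ICE_RING_D:
            prof = prof + _ICE_RING_AMP * np.exp(
                -(q - 1.0 / d_ring) ** 2 / (2 * _ICE_RING_WIDTH ** 2))
    return image + scene.background_scale * prof


def apply_detector(image: np.ndarray, scene: SimScene,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Convert a photon-expectation image to noisy integer detector counts.

    ``counts = Poisson(expectation) * gain + Gaussian(0, read_noise)``,
    clipped to [0, saturation] and integer-cast; then the beamstop disk is
    zeroed, bad-pixel regions get the -1 sentinel and hot pixels saturate.
    """
    if np.any(image < 0):
        raise RuntimeError("negative photon expectation (internal error)")
    rng = rng or np.random.default_rng(scene.noise_seed)
    det = scene.geometry.detector
    counts = rng.poisson(image).astype(np.float64) * det.gain
    if scene.read_noise > 0:
        counts += rng.normal(0.0, scene.read_noise, size=counts.shape)
    counts = np.clip(np.rint(counts), 0, det.saturation).astype(np.int32)
    if scene.geometry.beam.beamstop_mm > 0:
        r = pixel_radius_map(scene.geometry)
        counts[r <= scene.geometry.beam.beamstop_mm] = 0
    for s0, s1, f0, f1 in scene.bad_regions:
        counts[s0:s1, f0:f1] = MASK_SENTINEL
    if len(scene.hot_pixels):
        counts[scene.hot_pixels[:, 0], scene.hot_pixels[:, 1]] = det.saturation
    return counts


# -- full pipeline --------------------------------------------------------

def make_labeled_example(config: SimulationConfig,
                         rng: np.random.Generator) -> LabeledImage:
    """scene -> spots -> background -> detector, with ground-truth labels."""
    scene = sample_scene(config, rng)
    image = render_spots(scene, spot_sigma_px=config.spot_sigma_px)
    image = add_background(image, scene)
    pixels = apply_detector(image, scene)
    b = scene.ensemble.crystals[0].b_factor
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d = float(resolution_from_b(b, config.trend))
    return LabeledImage(pixels=pixels, inverse_resolution=1.0 / d,
                        n_lattices=scene.ensemble.n_lattices,
                        is_overlapped=scene.ensemble.n_lattices > 1,
                        b_factor=b, scene=scene)


def generate_examples(config: SimulationConfig, n: int, seed: int):
    """Yield ``n`` labeled images, reproducibly, from one master seed."""
    rng = np.random.default_rng(seed)
    for _ in range(n):
        yield make_labeled_example(config, rng)


def build_training_set(config: SimulationConfig, n: int, seed: int,
                       quadrant: str = "UL") -> dict:
    """Simulate and condition ``n`` images into a training-ready dict.

    Returns ``images`` (N, 512, 512) int16 conditioned quadrants (the
    configured training quadrant only), ``labels`` (inverse resolution in
    A^-1 for the resolution task, 0/1 flags for the overlap task) and
    per-image ``geometry`` arrays for the geometry output stage.
    """
    from .condition import QUADRANT_ORDER, condition_image
    qi = QUADRANT_ORDER.index(quadrant)
    images = np.empty((n, 512, 512), dtype=np.int16)
    labels = np.empty(n, dtype=np.float64)
    dist = np.empty(n, dtype=np.float64)
    for i, ex in enumerate(generate_examples(config, n, seed)):
        quads = condition_image(ex.pixels, ex.scene.geometry, quadrants=4)
        images[i] = quads[qi].pixels
        labels[i] = (ex.inverse_resolution if config.task == "resolution"
                     else float(ex.is_overlapped))
        dist[i] = ex.scene.geometry.distance_mm
    det = make_context(config.preset, 100.0).detector
    geometry = {
        "wavelength_A": np.full(n, config.wavelength_A),
        "p_eff_mm": np.full(n, det.effective_pixel_mm),
        "distance_mm": dist,
    }
    return {"images": images, "labels": labels, "geometry": geometry,
            "task": config.task, "quadrant": quadrant, "seed": seed}


def count_bragg_peaks(image: np.ndarray, threshold: float,
                      size: int = 5) -> int:
    """Brute-force local-maximum count above a threshold (noise-free renders)."""
    mx = ndimage.maximum_filter(image, size=size, mode="constant")
    peaks = (image == mx) & (image > threshold)
    return int(peaks.sum())
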