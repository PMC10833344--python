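"""Detector and beam geometry.

Flat-detector, normal-incidence geometry: a single rectangular panel of
square pixels sits perpendicular to the incident beam at a distance ``D``
(mm).  A pixel at radial distance ``r`` (mm) from the beam center records
scattering at angle ``2theta = arctan(r / D)`` and therefore probes the
Bragg resolution

    d = lambda / (2 sin(theta))          [Angstrom]

These conversions are used by the simulator (to place Bragg spots), by the
label generator (B factor -> resolution -> inverse resolution) and by the
geometry output stage of the resolution model, so they live in one module.

Coordinates are 0-based ``(slow, fast)`` array indices; the beam center is
stored in raw-pixel units and radii are measured from pixel centers.
Forward scattering (``r = 0``) is reported as a ``+inf`` resolution
sentinel rather than an error so that vectorized per-pixel maps are total.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import yaml

__all__ = [
    "GeometryError",
    "UnreachableResolutionError",
    "DetectorSpec",
    "BeamSpec",
    "GeometryContext",
    "DETECTOR_PRESETS",
    "make_context",
    "resolution_at_radius",
    "radius_at_resolution",
    "pixel_resolution_map",
    "pixel_radius_map",
]


class GeometryError(ValueError):
    """Invalid detector/beam geometry."""


class UnreachableResolutionError(GeometryError):
    """Requested resolution cannot be recorded by a flat detector."""


@dataclass(frozen=True)
class DetectorSpec:
    """Physical description of a (single-panel) area detector.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"pilatus6m"``.
    n_fast, n_slow : int
        Pixel counts along the fast and slow axes.
    pixel_mm : float
        Edge length of a (square) raw pixel in mm.
    downsample : int
        Block size ``N`` of the max-pool conditioning step; the effective
        conditioned pixel size is ``pixel_mm * downsample``.
    gain : float
        Detector units per detected photon.
    saturation : int
        Largest representable count.
    """

    name: str
    n_fast: int
    n_slow: int
    pixel_mm: float
    downsample: int = 2
    gain: float = 1.0
    saturation: int = 65535

    def __post_init__(self) -> None:
        if self.n_fast < 1 or self.n_slow < 1:
            raise GeometryError("pixel counts must be >= 1")
        if self.downsample < 1:
            raise GeometryError("downsample factor must be >= 1")
        if self.pixel_mm <= 0:
            raise GeometryError("pixel size must be positive")
        if self.gain <= 0:
            raise GeometryError("gain must be positive")

    @property
    def effective_pixel_mm(self) -> float:
        """Pixel size after block downsampling by ``downsample``."""
        return self.pixel_mm * self.downsample


@dataclass(frozen=True)
class BeamSpec:
    """Incident beam: wavelength, where it hits the detector, beamstop.

    ``flux_scale`` is a simulation-only knob: the expected photon count of
    the strongest (unit Debye-Waller, unit structure factor) reflection.
    """

    wavelength_A: float = 0.9795
    center_fast_px: float = 0.0
    center_slow_px: float = 0.0
    beamstop_mm: float = 0.0
    flux_scale: float = 1000.0

    def __post_init__(self) -> None:
        if self.wavelength_A <= 0:
            raise GeometryError("wavelength must be positive")
        if self.beamstop_mm < 0:
            raise GeometryError("beamstop radius must be >= 0")


@dataclass(frozen=True)
class GeometryContext:
    """Detector + beam + sample-to-detector distance (mm)."""

    detector: DetectorSpec
    beam: BeamSpec
    distance_mm: float

    def __post_init__(self) -> None:
        if self.distance_mm <= 0:
            raise GeometryError("detector distance must be positive")

    def with_distance(self, distance_mm: float) -> "GeometryContext":
        return replace(self, distance_mm=distance_mm)

    # -- flat key/value serialization ------------------------------------
    def to_config(self) -> dict:
        d, b = self.detector, self.beam
        return {
            "detector.name": d.name,
            "detector.nfast": d.n_fast,
            "detector.nslow": d.n_slow,
            "detector.pixel_mm": d.pixel_mm,
            "detector.downsample": d.downsample,
            "detector.gain": d.gain,
            "detector.saturation": d.saturation,
            "beam.wavelength_A": b.wavelength_A,
            "beam.center_fast_px": b.center_fast_px,
            "beam.center_slow_px": b.center_slow_px,
            "beam.beamstop_mm": b.beamstop_mm,
            "distance_mm": self.distance_mm,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "GeometryContext":
        det = DetectorSpec(
            name=str(cfg["detector.name"]),
            n_fast=int(cfg["detector.nfast"]),
            n_slow=int(cfg["detector.nslow"]),
            pixel_mm=float(cfg["detector.pixel_mm"]),
            downsample=int(cfg["detector.downsample"]),
            gain=float(cfg.get("detector.gain", 1.0)),
            saturation=int(cfg.get("detector.saturation", 65535)),
        )
        beam = BeamSpec(
            wavelength_A=float(cfg["beam.wavelength_A"]),
            center_fast_px=float(cfg["beam.center_fast_px"]),
            center_slow_px=float(cfg["beam.center_slow_px"]),
            beamstop_mm=float(cfg.get("beam.beamstop_mm", 0.0)),
        )
        return cls(detector=det, beam=beam, distance_mm=float(cfg["distance_mm"]))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_config(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "GeometryContext":
        return cls.from_config(yaml.safe_load(text))


#: Shipped detector presets.  Physical constants are configuration, not code:
#: these are convenience entries, and any field may be overridden.
DETECTOR_PRESETS: dict[str, DetectorSpec] = {
    "pilatus6m": DetectorSpec("pilatus6m", 2463, 2527, 0.172, downsample=2,
                              saturation=1048575),
    "eiger16m": DetectorSpec("eiger16m", 4148, 4362, 0.075, downsample=4,
                             saturation=65535),
    "rayonix340": DetectorSpec("rayonix340", 3840, 3840, 0.0885, downsample=4,
                               saturation=65535),
    # Desk-scale detector for tests and examples: coarse pixels so that a
    # 512x512 panel still spans wide scattering angles at 200-300 mm.
    "toy": DetectorSpec("toy", 512, 512, 0.5, downsample=2, saturation=65535),
}


def make_context(preset: str, distance_mm: float,
                 wavelength_A: float = 0.9795,
                 beam_center: tuple[float, float] | None = None,
                 beamstop_mm: float = 0.0) -> GeometryContext:
    """Build a :class:`GeometryContext` from a named detector preset.

    ``beam_center`` is ``(fast, slow)`` in raw pixels; default is the
    detector face center.
    """
    try:
        det = DETECTOR_PRESETS[preset]
    except KeyError:
        raise GeometryError(f"unknown detector preset {preset!r}") from None
    if beam_center is None:
        beam_center = ((det.n_fast - 1) / 2.0, (det.n_slow - 1) / 2.0)
    beam = BeamSpec(wavelength_A=wavelength_A,
                    center_fast_px=beam_center[0],
                    center_slow_px=beam_center[1],
                    beamstop_mm=beamstop_mm)
    return GeometryContext(detector=det, beam=beam, distance_mm=distance_mm)


def _check_geom(distance_mm, wavelength_A) -> None:
    if np.any(np.asarray(distance_mm) <= 0):
        raise GeometryError("detector distance must be positive")
    if np.any(np.asarray(wavelength_A) <= 0):
        raise GeometryError("wavelength must be positive")


def resolution_at_radius(r_mm, distance_mm, wavelength_A):
    """Bragg resolution d (A) recorded at radius ``r_mm`` from the beam center.

    ``d = lambda / (2 sin(0.5 arctan(r/D)))``; ``r = 0`` maps to ``+inf``.
    Accepts scalars or arrays (vectorized, total on r >= 0).
    """
    _check_geom(distance_mm, wavelength_A)
    r = np.asarray(r_mm, dtype=float)
    if np.any(r < 0):
        raise GeometryError("radius must be >= 0")
    theta = 0.5 * np.arctan2(r, distance_mm)
    with np.errstate(divide="ignore"):
        d = np.where(theta > 0, wavelength_A / (2.0 * np.sin(np.where(theta > 0, theta, 1.0))), np.inf)
    if d.ndim == 0:
        return float(d)
    return d


def radius_at_resolution(d_A, distance_mm, wavelength_A):
    """Radius (mm) on a flat detector where resolution ``d_A`` is recorded.

    Inverse of :func:`resolution_at_radius`:
    ``r = D tan(2 arcsin(lambda / 2d))``.  Raises
    :class:`UnreachableResolutionError` when the Bragg condition is not
    solvable (``d < lambda/2``) or the scattering angle reaches 90 deg,
    beyond the horizon of a flat detector at normal incidence
    (``d <= lambda / sqrt(2)``).
    """
    _check_geom(distance_mm, wavelength_A)
    d = np.asarray(d_A, dtype=float)
    sin_t = wavelength_A / (2.0 * d)
    if np.any(sin_t > 1.0):
        raise UnreachableResolutionError("d < lambda/2: Bragg condition unsolvable")
    two_theta = 2.0 * np.arcsin(sin_t)
    if np.any(two_theta >= np.pi / 2):
        raise UnreachableResolutionError(
            "scattering angle >= 90 deg: outside flat-detector horizon")
    r = distance_mm * np.tan(two_theta)
    if r.ndim == 0:
        return float(r)
    return r


def pixel_radius_map(ctx: GeometryContext, downsampled: bool = False) -> np.ndarray:
    """Radial distance (mm) from the beam center for every pixel center.

    With ``downsampled=True`` the map is on the block-pixel grid (effective
    pixel size ``p*N``); the beam center is converted accordingly.
    """
    det = ctx.detector
    n = det.downsample if downsampled else 1
    p = det.pixel_mm * n
    n_fast = -(-det.n_fast // n)
    n_slow = -(-det.n_slow // n)
    cf = ctx.beam.center_fast_px / n
    cs = ctx.beam.center_slow_px / n
    fast = (np.arange(n_fast) - cf) * p
    slow = (np.arange(n_slow) - cs) * p
    return np.hypot(slow[:, None], fast[None, :])


def pixel_resolution_map(ctx: GeometryContext, downsampled: bool = False) -> np.ndarray:
    """Per-pixel Bragg resolution (A); ``+inf`` at the beam-center pixel."""
    r = pixel_radius_map(ctx, downsampled=downsampled)
    return resolution_at_radius(r, ctx.distance_mm, ctx.beam.wavelength_A)
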