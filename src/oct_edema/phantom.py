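"""Synthetic OCT-like B-scan phantoms with known ground truth.

A phantom emulates the geometry of a macular B-scan: a bright, optionally
curved retinal band on a dark vitreous/choroid background, containing one or
more dark (hypo-reflective) elliptical fluid cavities that stand in for
macular edema.  The observation model is

    I(x, y) = S(x, y) * N_s(x, y) + N_b(x, y)

with ``S`` the piecewise-constant clean reflectance, ``N_s`` unit-mean
multiplicative speckle and ``N_b`` zero-mean additive background noise.
Speckle is drawn from a gamma distribution with shape ``k`` and scale
``1/k`` (mean 1, variance ``1/k``), the standard positive multiplicative
model for incoherently averaged speckle; the background noise is Gaussian.

All intensities live in [0, 1]; 8/16-bit integer images are rescaled at the
I/O boundary (:mod:`oct_edema.imgio`).  Pixel centers sit at integer
coordinates, row-major and 0-based; ellipse membership is evaluated at pixel
centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "PhantomPair",
    "default_spec",
    "render_clean",
    "apply_speckle",
    "generate_phantom",
]


class PhantomGeometryError(ValueError):
    """Raised when a phantom's geometry violates its invariants."""


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse: center (row, col) and semi-axes in pixels."""

    center_row: float
    center_col: float
    semi_row: float
    semi_col: float

    def __post_init__(self) -> None:
        if self.semi_row <= 0 or self.semi_col <= 0:
            raise PhantomGeometryError(f"ellipse semi-axes must be positive: {self}")

    def mask(self, height: int, width: int) -> np.ndarray:
        rr, cc = np.mgrid[0:height, 0:width]
        return (
            ((rr - self.center_row) / self.semi_row) ** 2
            + ((cc - self.center_col) / self.semi_col) ** 2
        ) <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic B-scan.

    ``retina_band`` gives the (top, bottom) rows (inclusive) of the bright
    layer; ``band_curvature`` adds a smooth downward vertical offset profile
    peaking mid-scan, a crude stand-in for foveal curvature.  Intensities are
    mean reflectances in [0, 1] and must satisfy
    background < edema < retina.  ``speckle_shape`` is the gamma shape of the
    unit-mean multiplicative speckle (smaller = noisier);
    ``background_noise_sd`` the additive Gaussian noise level.
    """

    height: int = 128
    width: int = 256
    retina_band: tuple[int, int] = (36, 91)
    band_curvature: float = 4.0
    edema_regions: tuple[Ellipse, ...] = field(
        default_factory=lambda: (
            Ellipse(66, 88, 11.0, 24.0),
            Ellipse(64, 176, 9.0, 18.0),
        )
    )
    intensity_retina: float = 0.78
    intensity_edema: float = 0.22
    intensity_background: float = 0.06
    speckle_shape: float = 4.0
    background_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise PhantomGeometryError("image dimensions must be positive")
        top, bottom = self.retina_band
        if not 0 <= top < bottom < self.height:
            raise PhantomGeometryError(f"retina band {self.retina_band} outside image")
        if not (
            0.0 <= self.intensity_background < self.intensity_edema < self.intensity_retina <= 1.0
        ):
            raise PhantomGeometryError(
                "intensities must satisfy 0 <= background < edema < retina <= 1, got "
                f"{self.intensity_background}, {self.intensity_edema}, {self.intensity_retina}"
            )
        if self.speckle_shape <= 0:
            raise PhantomGeometryError("speckle_shape must be > 0")
        if self.background_noise_sd < 0:
            raise PhantomGeometryError("background_noise_sd must be >= 0")
        if self.band_curvature < 0:
            raise PhantomGeometryError("band_curvature must be >= 0")

    def band_offset(self) -> np.ndarray:
        """Per-column vertical offset of the retina band (0 at the edges)."""
        x = np.linspace(0.0, np.pi, self.width)
        return self.band_curvature * np.sin(x) ** 2


@dataclass(frozen=True)
class PhantomPair:
    """A speckled image with its clean original and ground-truth masks."""

    image: np.ndarray
    clean: np.ndarray
    retina_mask: np.ndarray
    edema_mask: np.ndarray

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.image, self.clean, self.retina_mask, self.edema_mask)}
        if len(shapes) != 1:
            raise ValueError(f"mismatched shapes in PhantomPair: {shapes}")
        if np.any(self.edema_mask & ~self.retina_mask):
            raise ValueError("edema_mask must be a subset of retina_mask")
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("image values must lie in [0, 1]")


def default_spec(**overrides) -> PhantomSpec:
    """The package's reference phantom: 128x256, speckle shape 4."""
    return PhantomSpec(**overrides)


def render_clean(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rasterize the noise-free reflectance map S and its ground-truth masks.

    Deterministic: uses no randomness.  Raises
    :class:`PhantomGeometryError` naming the first edema ellipse that is not
    fully contained in the retina band.
    """
    offset = spec.band_offset()
    rr = np.arange(spec.height)[:, None].astype(float)
    top, bottom = spec.retina_band
    retina_mask = (rr >= top + offset[None, :]) & (rr <= bottom + offset[None, :])

    edema_mask = np.zeros((spec.height, spec.width), dtype=bool)
    for i, ell in enumerate(spec.edema_regions):
        m = ell.mask(spec.height, spec.width)
        if not m.any():
            raise PhantomGeometryError(f"edema ellipse #{i} ({ell}) rasterizes to nothing")
        if np.any(m & ~retina_mask):
            raise PhantomGeometryError(
                f"edema ellipse #{i} ({ell}) is not contained in the retina band"
            )
        edema_mask |= m

    clean = np.full((spec.height, spec.width), spec.intensity_background, dtype=float)
    clean[retina_mask] = spec.intensity_retina
    clean[edema_mask] = spec.intensity_edema
    return clean, retina_mask, edema_mask


def apply_speckle(
    clean: np.ndarray,
    speckle_shape: float,
    background_noise_sd: float,
    seed: int,
) -> np.ndarray:
    """Corrupt a clean image with multiplicative speckle plus additive noise.

    Returns ``clip(clean * m + b, 0, 1)`` where ``m`` is i.i.d. gamma with
    the given shape and scale ``1/shape`` (unit mean) and ``b`` is i.i.d.
    zero-mean Gaussian with the given standard deviation.  The same seed
    yields a bit-identical array.
    """
    clean = np.asarray(clean, dtype=float)
    if speckle_shape <= 0:
        raise ValueError("speckle_shape must be > 0")
    if background_noise_sd < 0:
        raise ValueError("background_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    m = rng.gamma(speckle_shape, 1.0 / speckle_shape, size=clean.shape)
    b = rng.normal(0.0, background_noise_sd, size=clean.shape)
    return np.clip(clean * m + b, 0.0, 1.0)


def generate_phantom(spec: PhantomSpec) -> PhantomPair:
    """Render the clean geometry and corrupt it per the spec's noise model."""
    clean, retina_mask, edema_mask = render_clean(spec)
    image = apply_speckle(clean, spec.speckle_shape, spec.background_noise_sd, spec.seed)
    return PhantomPair(image=image, clean=clean, retina_mask=retina_mask, edema_mask=edema_mask)
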