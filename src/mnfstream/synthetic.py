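"""Synthetic skin-like hyperspectral phantoms and SAM-based scoring.

The simulation design mirrors a standard benchmark for line-scan
denoisers: a cube partitioned into a grid of rectangular blocks, every
pixel in a block carrying the same smooth diffuse-reflectance spectrum,
plus additive zero-mean Gaussian noise of constant variance.  The clean
cube is the gold standard; denoisers are scored with the spectral angle
mapper (SAM), the arccosine of the normalised inner product of two
spectra — scale-invariant, in radians.

Skin reflectance is emulated parametrically: a smooth baseline shaped by
dermal scattering, attenuated by melanin (a broad short-wavelength slope)
and by haemoglobin (absorption bands near 542/577 nm when oxygenated,
556/760 nm when deoxygenated).  The per-block spectra are produced by
varying the three physiological parameters — melanin optical density,
blood volume fraction, oxygen saturation — one at a time around a baseline,
so the between-block signal lives in a low-dimensional spectral subspace,
as it does for real skin.  This emulates the smoothness and similarity of
skin spectra, not any particular tissue's absolute reflectance.

Default full-scale geometry is 800 lines x 900 samples x 160 bands in a
4 x 3 block grid; the CI-scale default (200 x 240 x 80, same grid) keeps
every property checkable in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "SyntheticSpec",
    "SAMReport",
    "make_skin_spectra",
    "make_block_image",
    "add_noise",
    "sam",
    "pairwise_sam",
    "sam_map",
    "sam_profile",
    "ci_spec",
    "full_spec",
]

#: noise variances of the three standard scenarios
NOISE_SCENARIOS = (0.01, 0.001, 0.0001)


@dataclass
class SyntheticSpec:
    """Geometry, spectra, noise level and seed of a simulated cube."""

    lines: int = 800
    samples: int = 900
    bands: int = 160
    block_grid: Tuple[int, int] = (4, 3)  # (rows along lines, cols along samples)
    noise_variance: float = 0.0001
    seed: int = 0
    wavelength_range: Tuple[float, float] = (400.0, 1000.0)
    spectra: Optional[np.ndarray] = None  # (rows*cols, bands); generated if None

    def __post_init__(self) -> None:
        rows, cols = self.block_grid
        if self.lines % rows or self.samples % cols:
            raise ValueError(
                f"grid {self.block_grid} does not divide "
                f"{self.lines} lines x {self.samples} samples"
            )
        if self.noise_variance < 0:
            raise ValueError("noise variance must be nonnegative")
        if self.spectra is not None:
            self.spectra = np.asarray(self.spectra, dtype=float)
            if self.spectra.shape != (rows * cols, self.bands):
                raise ValueError("spectra matrix must be (rows*cols, bands)")

    @property
    def n_blocks(self) -> int:
        return self.block_grid[0] * self.block_grid[1]

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(*self.wavelength_range, self.bands)


def ci_spec(noise_variance: float = 0.0001, seed: int = 0) -> SyntheticSpec:
    """Scaled-down cube (200 x 240 x 80, 4 x 3 grid) for fast runs."""
    return SyntheticSpec(
        lines=200, samples=240, bands=80, noise_variance=noise_variance, seed=seed
    )


def full_spec(noise_variance: float = 0.0001, seed: int = 0) -> SyntheticSpec:
    """Full-scale cube (800 x 900 x 160, 4 x 3 grid)."""
    return SyntheticSpec(noise_variance=noise_variance, seed=seed)


# ---------------------------------------------------------------------------
# spectra


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _skin_reflectance(
    wl: np.ndarray, melanin: float, blood: float, oxy: float, min_width: float
) -> np.ndarray:
    """Parametric diffuse reflectance of a skin-like medium on grid *wl* (nm).

    Feature widths are floored at *min_width* so the curve stays resolved
    (and hence smooth) on coarse band grids.
    """

    def w(width_nm: float) -> float:
        return max(width_nm, min_width)

    # scattering-shaped baseline: rises through the visible to a NIR plateau
    base = 0.30 + 0.45 * _sigmoid((wl - 580.0) / w(70.0))
    # melanin: broad absorption decaying with wavelength
    a_mel = melanin * np.exp(-(wl - 400.0) / w(270.0))
    # haemoglobin bands (oxygenated vs deoxygenated)
    a_oxy = _gauss(wl, 542.0, w(22.0)) + 1.1 * _gauss(wl, 577.0, w(18.0))
    a_deoxy = _gauss(wl, 556.0, w(28.0)) + 0.35 * _gauss(wl, 760.0, w(38.0))
    a_blood = blood * (oxy * a_oxy + (1.0 - oxy) * a_deoxy)
    return base * np.exp(-(a_mel + a_blood))


# baseline parameters (melanin, blood, oxygen) and one-at-a-time offset
# ladders.  Offsets are small perturbations: the reflectance response stays
# approximately linear in the parameters, so the 12 block spectra span an
# (essentially) 3-dimensional subspace — the low-dimensional spectral
# variability characteristic of healthy skin.  They also stay inside the
# physical bounds without clipping (which would collapse distinct blocks
# onto the same spectrum).
_BASE_PARAMS = np.array([0.55, 0.55, 0.70])
_PARAM_LO = np.array([0.10, 0.10, 0.05])
_PARAM_HI = np.array([1.30, 1.20, 0.95])
_PARAM_LADDERS = (
    (0.125, -0.125, 0.275, -0.235),   # melanin optical density
    (0.110, -0.110, 0.250, -0.190),   # blood volume fraction
    (0.160, -0.190, -0.360, -0.540),  # oxygen saturation
)


def make_skin_spectra(
    n: int,
    bands: int,
    seed: int,
    wavelength_range: Tuple[float, float] = (400.0, 1000.0),
) -> np.ndarray:
    """Generate *n* smooth, mutually distinguishable skin-like spectra.

    Spectrum 0 is the baseline; spectrum j varies physiological parameter
    (j-1) mod 3 by a graded, sign-alternating step plus a small seeded
    jitter, emulating a one-parameter-at-a-time simulation design.
    Guarantees: values within [0.02, 0.98], max |second difference| < 0.01
    per band step, pairwise SAM >= 0.01 rad.
    """
    if n < 1:
        raise ValueError("need at least one spectrum")
    if bands < 8:
        raise ValueError("need at least 8 bands for a resolved spectrum")
    wl = np.linspace(*wavelength_range, bands)
    step_nm = (wavelength_range[1] - wavelength_range[0]) / (bands - 1)
    min_width = 5.0 * step_nm
    rng = np.random.default_rng(seed)

    params = np.empty((n, 3))
    params[0] = _BASE_PARAMS
    for j in range(1, n):
        k = (j - 1) % 3
        cycle = (j - 1) // 3
        p = _BASE_PARAMS.copy()
        ladder = _PARAM_LADDERS[k]
        if cycle < len(ladder):
            p[k] += ladder[cycle]
        else:  # beyond the designed 12: draw uniformly inside the bounds
            p[k] = rng.uniform(_PARAM_LO[k], _PARAM_HI[k])
        p += rng.normal(0.0, 0.005, size=3)
        params[j] = np.clip(p, _PARAM_LO, _PARAM_HI)

    # widen features until the discrete smoothness bound holds (coarse band
    # grids need broader features, as physical band-averaging would give)
    for _ in range(8):
        spectra = np.array(
            [_skin_reflectance(wl, m, b, s, min_width) for m, b, s in params]
        )
        if np.abs(np.diff(spectra, n=2, axis=1)).max() < 0.009:
            break
        min_width *= 1.4
    else:
        raise ValueError("generated spectra violate the smoothness bound")
    if spectra.min() < 0.02 or spectra.max() > 0.98:
        raise ValueError("generated spectra left the [0.02, 0.98] range")
    if n > 1:
        angles = pairwise_sam(spectra)
        off = angles[~np.eye(n, dtype=bool)]
        if off.min() < 0.01:
            raise ValueError(
                "spectra not separable: increase n/bands or parameter spread"
            )
    return spectra


# ---------------------------------------------------------------------------
# cube construction


def make_block_image(spec: SyntheticSpec) -> np.ndarray:
    """Noise-free block cube ``(lines, samples, bands)``.

    Block (i, j) of the grid (row-major) carries spectrum row
    ``i * cols + j`` exactly.
    """
    rows, cols = spec.block_grid
    spectra = spec.spectra
    if spectra is None:
        spectra = make_skin_spectra(
            spec.n_blocks, spec.bands, spec.seed, spec.wavelength_range
        )
    bl = spec.lines // rows
    bs = spec.samples // cols
    cube = np.empty((spec.lines, spec.samples, spec.bands))
    for i in range(rows):
        for j in range(cols):
            cube[i * bl : (i + 1) * bl, j * bs : (j + 1) * bs, :] = spectra[
                i * cols + j
            ]
    return cube


def add_noise(
    cube: np.ndarray, variance: float, seed: int, clip: bool = False
) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise of the given variance.

    Unclipped by default so the residual is exactly Gaussian; ``clip=True``
    bounds the result to [0, 1] as a camera simulation would.
    """
    if variance < 0:
        raise ValueError("variance must be nonnegative")
    cube = np.asarray(cube, dtype=float)
    if variance == 0:
        return cube.copy()
    rng = np.random.default_rng(seed)
    noisy = cube + rng.normal(0.0, np.sqrt(variance), size=cube.shape)
    if clip:
        noisy = np.clip(noisy, 0.0, 1.0)
    return noisy


# ---------------------------------------------------------------------------
# spectral angle mapper


def sam(a: np.ndarray, b: np.ndarray) -> float:
    """Spectral angle between two spectra, in radians [0, pi]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("SAM undefined for a zero spectrum")
    return float(np.arccos(np.clip(a @ b / (na * nb), -1.0, 1.0)))


def pairwise_sam(spectra: np.ndarray) -> np.ndarray:
    """Symmetric n x n matrix of spectral angles between rows."""
    S = np.asarray(spectra, dtype=float)
    norms = np.linalg.norm(S, axis=1)
    if np.any(norms == 0):
        raise ValueError("SAM undefined for a zero spectrum")
    G = (S @ S.T) / np.outer(norms, norms)
    return np.arccos(np.clip(G, -1.0, 1.0))


def sam_map(cube: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Per-pixel SAM between two ``(lines, samples, bands)`` cubes."""
    x = np.asarray(cube, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    nx = np.linalg.norm(x, axis=2)
    ny = np.linalg.norm(y, axis=2)
    if np.any(nx == 0) or np.any(ny == 0):
        raise ValueError("SAM undefined for zero spectra")
    cos = np.einsum("lpb,lpb->lp", x, y) / (nx * ny)
    return np.arccos(np.clip(cos, -1.0, 1.0))


@dataclass
class SAMReport:
    """Per-pixel map, per-line mean profile and overall summary, in radians."""

    map: np.ndarray      # (lines, samples), masked-out samples NaN
    profile: np.ndarray  # (lines,) mean over masked samples
    mean: float
    median: float


def sam_profile(
    cube: np.ndarray, reference: np.ndarray, mask: Optional[np.ndarray] = None
) -> SAMReport:
    """Per-line mean SAM between two cubes over an optional region mask.

    *mask* may be a boolean vector over samples (e.g. the rightmost block
    column) or a full (lines, samples) boolean array.
    """
    amap = sam_map(cube, reference)
    L, P = amap.shape
    if mask is None:
        m = np.ones((L, P), dtype=bool)
    else:
        m = np.asarray(mask, dtype=bool)
        if m.shape == (P,):
            m = np.broadcast_to(m, (L, P))
        elif m.shape != (L, P):
            raise ValueError("mask must cover samples or (lines, samples)")
    if not m.any():
        raise ValueError("empty mask")
    masked = np.where(m, amap, np.nan)
    with np.errstate(invalid="ignore"):
        profile = np.nanmean(masked, axis=1)
    values = amap[m]
    return SAMReport(
        map=masked,
        profile=profile,
        mean=float(values.mean()),
        median=float(np.median(values)),
    )
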