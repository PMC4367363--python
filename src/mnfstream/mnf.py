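"""Minimum-noise-fraction transform: eigenproblem, SNR ordering, denoising.

Model: an image matrix Y (bands x pixels) with additive noise, Y = S + N.
Zero-mean the rows to get Z and look for the linear combinations a'Z that
minimise the noise fraction.  These are the solutions of the generalized
symmetric-definite eigenproblem

    Sigma_N a = lambda Sigma a

where Sigma is the image covariance and Sigma_N the noise covariance.
Sorting eigenpairs by ascending eigenvalue orders components by decreasing
SNR, since SNR_j = a_j' Sigma a_j / a_j' Sigma_N a_j - 1 = 1/lambda_j - 1.
Denoising keeps the first r components in the inverse transform:

    Z* = (A^-1)' R A' Z = D Z,   R = diag(1,...,1,0,...,0)  (r ones)

D is an (oblique) projection acting independently on each pixel spectrum,
which is what makes a per-line streaming variant possible at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import scipy.linalg

from .config import DenoiseConfig, RetentionPolicy
from .stats import RunningMoments, covariance, line_moments, merge_moments, noise_line

__all__ = [
    "MNFModel",
    "DenoisingMatrix",
    "BatchResult",
    "solve_mnf",
    "band_snr",
    "signal_fraction",
    "choose_r",
    "denoising_matrix",
    "forward_transform",
    "apply_denoise",
    "denoise_batch",
    "component_table",
]

#: relative symmetry tolerance accepted for input covariance matrices
_SYM_RTOL = 1e-8


class EigensolveError(np.linalg.LinAlgError):
    """The generalized eigenproblem could not be solved (degenerate Sigma)."""


@dataclass
class MNFModel:
    """Solved transform: eigenvectors (columns of A, ascending eigenvalue),
    eigenvalues, the centering mean and the covariances that produced them."""

    transform: np.ndarray        # A, bands x bands
    eigenvalues: np.ndarray      # lambda, ascending
    mean: np.ndarray
    sigma: np.ndarray
    sigma_noise: np.ndarray
    regularized: bool = False
    reg_eps: float = 0.0

    @property
    def bands(self) -> int:
        return self.transform.shape[0]

    @property
    def snr(self) -> np.ndarray:
        """Raw per-component SNR, 1/lambda - 1 (may be negative)."""
        return band_snr(self)


@dataclass
class DenoisingMatrix:
    """D = (A^-1)' R A' with R keeping the first r components; idempotent."""

    matrix: np.ndarray
    r: int


@dataclass
class BatchResult:
    cube: np.ndarray
    model: MNFModel
    dmatrix: DenoisingMatrix

    @property
    def r(self) -> int:
        return self.dmatrix.r


def _check_symmetric(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square")
    scale = np.linalg.norm(M)
    if scale > 0 and np.linalg.norm(M - M.T) > _SYM_RTOL * scale:
        raise ValueError(f"{name} is not symmetric")
    return 0.5 * (M + M.T)


def solve_mnf(
    sigma: np.ndarray,
    sigma_noise: np.ndarray,
    mean: Optional[np.ndarray] = None,
    reg_eps: float = 1e-10,
) -> MNFModel:
    """Solve Sigma_N a = lambda Sigma a, eigenpairs sorted by ascending lambda.

    If Sigma is numerically singular it is ridged by
    ``reg_eps * trace(Sigma)/B * I`` before solving and the model records
    that it was.  Raises :class:`EigensolveError` if the pencil remains
    unsolvable (e.g. a constant image).
    """
    sigma = _check_symmetric(sigma, "sigma")
    sigma_noise = _check_symmetric(sigma_noise, "sigma_noise")
    if sigma.shape != sigma_noise.shape:
        raise ValueError("sigma and sigma_noise must have the same shape")
    B = sigma.shape[0]
    if mean is None:
        mean = np.zeros(B)
    mean = np.asarray(mean, dtype=float)
    if not sigma.any() or not sigma_noise.any():
        raise EigensolveError(
            "degenerate covariance (constant image or zero noise estimate)"
        )

    regularized = False
    ridge = 0.0
    try:
        w, V = scipy.linalg.eigh(sigma_noise, sigma)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError, ValueError):
        ridge = reg_eps * (np.trace(sigma) / B if np.trace(sigma) > 0 else 1.0)
        sigma = sigma + ridge * np.eye(B)
        regularized = True
        try:
            w, V = scipy.linalg.eigh(sigma_noise, sigma)
        except (scipy.linalg.LinAlgError, np.linalg.LinAlgError, ValueError) as exc:
            raise EigensolveError(
                "sigma not positive definite even after regularization"
            ) from exc

    # eigh returns ascending eigenvalues; enforce a stable order anyway so
    # exact ties keep their index order
    order = np.argsort(w, kind="stable")
    w, V = w[order], V[:, order]
    if regularized:
        # with a'(Sigma + ridge I)a = 1, directions whose image variance is
        # pure ridge satisfy ridge*||a||^2 ~ 1: they carry no signal at all
        # and must not occupy leading (high-SNR) positions
        vacuous = ridge * (V**2).sum(axis=0) >= 0.5
        if vacuous.any():
            keep = np.flatnonzero(~vacuous)
            drop = np.flatnonzero(vacuous)
            reorder = np.concatenate([keep, drop])
            w, V = w[reorder], V[:, reorder]
    return MNFModel(
        transform=V,
        eigenvalues=w,
        mean=mean,
        sigma=sigma,
        sigma_noise=sigma_noise,
        regularized=regularized,
        reg_eps=reg_eps,
    )


def band_snr(model: MNFModel, clamp: bool = False) -> np.ndarray:
    """Per-component SNR = 1/lambda - 1, non-increasing in component index."""
    with np.errstate(divide="ignore"):
        snr = 1.0 / model.eigenvalues - 1.0
    snr = np.where(np.isfinite(snr), snr, np.inf)
    if clamp:
        snr = np.maximum(snr, 0.0)
    return snr


def signal_fraction(model: MNFModel, r: int) -> float:
    """Fraction of total signal conserved by keeping the first r components.

    Uses clamped (nonnegative) SNRs so over-estimated noise cannot make the
    fraction exceed 1.
    """
    B = model.bands
    if not 1 <= r <= B:
        raise ValueError(f"r must be in [1, {B}], got {r}")
    snr = band_snr(model, clamp=True)
    total = snr.sum()
    if total <= 0:
        raise ValueError("all component SNRs are zero: signal fraction undefined")
    return float(snr[:r].sum() / total)


def choose_r(model: MNFModel, policy: RetentionPolicy) -> int:
    """Pick the number of retained components under the given policy."""
    B = model.bands
    if policy.kind == "fixed":
        r = int(policy.value)
        if not 1 <= r <= B:
            raise ValueError(f"fixed r={r} outside [1, {B}]")
        return r
    if policy.kind == "min_snr":
        snr = band_snr(model)
        above = np.nonzero(snr >= policy.value)[0]
        return int(above[-1]) + 1 if above.size else 1
    if policy.kind == "min_fraction":
        snr = band_snr(model, clamp=True)
        total = snr.sum()
        if total <= 0:
            raise ValueError("all component SNRs are zero: signal fraction undefined")
        frac = np.cumsum(snr) / total
        return int(np.searchsorted(frac, policy.value - 1e-12)) + 1
    # gap: largest relative jump in the ascending eigenvalue sequence
    lam = np.maximum(model.eigenvalues, model.eigenvalues.max() * 1e-15)
    if B == 1:
        return 1
    ratios = lam[1:] / lam[:-1]
    return int(np.argmax(ratios)) + 1


def denoising_matrix(model: MNFModel, r: int) -> DenoisingMatrix:
    """Build D = (A^-1)' R A' keeping the first r (highest-SNR) components."""
    B = model.bands
    if not 1 <= r <= B:
        raise ValueError(f"r must be in [1, {B}], got {r}")
    A = model.transform
    try:
        Ainv = scipy.linalg.inv(A)
    except scipy.linalg.LinAlgError as exc:
        raise EigensolveError("transform matrix is singular") from exc
    lam = model.eigenvalues
    if r < B:
        lo, hi = abs(lam[r - 1]), abs(lam[r])
        if hi > 0 and abs(lam[r] - lam[r - 1]) <= 1e-10 * max(lo, hi):
            warnings.warn(
                f"retention cut r={r} falls inside a cluster of equal "
                "eigenvalues; the projection is basis-dependent",
                RuntimeWarning,
                stacklevel=2,
            )
    D = Ainv.T[:, :r] @ A[:, :r].T
    return DenoisingMatrix(matrix=D, r=r)


def forward_transform(model: MNFModel, pixels: np.ndarray) -> np.ndarray:
    """Component scores T = A' Z for bands x pixels data."""
    Z = np.asarray(pixels, dtype=float) - model.mean[:, None]
    return model.transform.T @ Z


def apply_denoise(
    dmatrix: DenoisingMatrix,
    pixels: np.ndarray,
    mean: np.ndarray,
    emit_zero_meaned: bool = False,
) -> np.ndarray:
    """Denoise bands x pixels data: D (Y - mu) [+ mu]."""
    Z = np.asarray(pixels, dtype=float) - mean[:, None]
    out = dmatrix.matrix @ Z
    if not emit_zero_meaned:
        out += mean[:, None]
    return out


def denoise_batch(
    cube: np.ndarray, config: Optional[DenoiseConfig] = None
) -> BatchResult:
    """Conventional full-image MNF denoising.

    *cube* is ``(lines, samples, bands)``.  Image moments are accumulated
    over all pixels and noise moments over all within-line adjacent-sample
    differences, exactly as the streaming denoiser would at the end of the
    image; the eigenproblem is then solved once and the truncated inverse
    transform applied to every pixel.  Means are restored in the output
    unless ``config.emit_zero_meaned``.
    """
    if config is None:
        config = DenoiseConfig()
    cube = np.asarray(cube, dtype=float)
    if cube.ndim != 3:
        raise ValueError("cube must be (lines, samples, bands)")
    L, P, B = cube.shape
    img = RunningMoments.zero(B)
    noise = RunningMoments.zero(B)
    for i in range(L):
        line = cube[i].T  # bands x samples
        img = merge_moments(img, line_moments(line))
        if P >= 2:
            noise = merge_moments(
                noise, line_moments(noise_line(line, config.noise_convention))
            )
    if noise.n == 0:
        raise ValueError("cube has fewer than 2 samples per line: no noise estimate")
    model = solve_mnf(
        covariance(img), covariance(noise), mean=img.mean, reg_eps=config.reg_eps
    )
    r = choose_r(model, config.policy)
    dmat = denoising_matrix(model, r)
    Y = cube.reshape(L * P, B).T
    out = apply_denoise(dmat, Y, model.mean, config.emit_zero_meaned)
    return BatchResult(cube=out.T.reshape(L, P, B), model=model, dmatrix=dmat)


def component_table(model: MNFModel, r: Optional[int] = None) -> pd.DataFrame:
    """Eigenvalue/SNR table (component, lambda, snr, cumulative fraction)."""
    snr = band_snr(model, clamp=True)
    total = snr.sum()
    cumfrac = np.cumsum(snr) / total if total > 0 else np.full(model.bands, np.nan)
    df = pd.DataFrame(
        {
            "component": np.arange(model.bands),
            "eigenvalue": model.eigenvalues,
            "snr": band_snr(model),
            "cumulative_fraction": cumfrac,
        }
    )
    if r is not None:
        df["retained"] = df["component"] < r
    return df
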