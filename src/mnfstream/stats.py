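"""Numerically stable streaming moments and the shift-difference noise signal.

The band covariance of a growing image cannot safely be accumulated as
``E[xy] - E[x]E[y]``: for data riding on a large offset the two sums agree
in their leading digits and the subtraction suffers catastrophic
cancellation.  Instead a per-line *co-moment* matrix (sum of centered outer
products, i.e. covariance times pixel count) is computed two-pass within
each line and merged across lines with the pairwise update

    C_curr = C_prev + C_line + outer(d, d) * N_line * N_prev / N_curr
    mu_curr = mu_prev + (N_line / N_curr) * (mu_line - mu_prev)

with ``d = mu_line - mu_prev`` — differences only, no large cancelling sums.

The noise signal is estimated from differences of spatially adjacent
samples within a line (valid when neighbouring pixels are spectrally
correlated, as in high-resolution skin images): ``n_{b,p} = c * (y_{b,p} -
y_{b,p+1})``.  With ``c = 1/sqrt(2)`` the differences have exactly the noise
covariance for i.i.d. additive noise; ``c = 1/2`` is the other convention in
circulation and halves the estimated variance.  Both are offered; the
resulting denoising matrix is identical either way because scaling the
noise covariance scales every eigenvalue equally.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Union

import numpy as np

from .envi import LineBlock

__all__ = [
    "RunningMoments",
    "NoiseConvention",
    "line_moments",
    "merge_moments",
    "covariance",
    "noise_line",
]


class NoiseConvention(Enum):
    """Prefactor applied to adjacent-sample differences."""

    HALF = "half"          # paper-literal 1/2: estimates half the noise variance
    INV_SQRT2 = "inv_sqrt2"  # unbiased 1/sqrt(2)

    @property
    def scale(self) -> float:
        return 0.5 if self is NoiseConvention.HALF else 1.0 / math.sqrt(2.0)


def _values(block: Union[LineBlock, np.ndarray]) -> np.ndarray:
    v = block.values if isinstance(block, LineBlock) else np.asarray(block)
    return np.asarray(v, dtype=np.float64)


@dataclass
class RunningMoments:
    """Pixel count, per-band mean and band x band co-moment matrix.

    ``comoment`` is the sum of centered outer products, i.e. the population
    covariance times ``n``; it is the quantity that merges stably.
    ``mean_comp`` carries the low-order bits of the mean (a two-sum
    compensation term): for data riding on a large offset the stored mean
    alone is only ulp-accurate, and those ulps, squared into the co-moment
    at every merge, would otherwise dominate the error.
    """

    n: int
    mean: np.ndarray
    comoment: np.ndarray
    mean_comp: Union[np.ndarray, None] = None

    @classmethod
    def zero(cls, bands: int) -> "RunningMoments":
        return cls(0, np.zeros(bands), np.zeros((bands, bands)), np.zeros(bands))

    def _comp(self) -> np.ndarray:
        return np.zeros_like(self.mean) if self.mean_comp is None else self.mean_comp

    @property
    def bands(self) -> int:
        return self.mean.shape[0]

    def covariance(self) -> np.ndarray:
        return covariance(self)

    def merge(self, other: "RunningMoments") -> "RunningMoments":
        return merge_moments(self, other)

    def copy(self) -> "RunningMoments":
        return RunningMoments(
            self.n, self.mean.copy(), self.comoment.copy(), self._comp().copy()
        )

    # -- persistence (resume of an interrupted stream) ---------------------

    def save(self, path) -> None:
        payload = {
            "n": int(self.n),
            "mean": self.mean.tolist(),
            "comoment": self.comoment.tolist(),
            "mean_comp": self._comp().tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "RunningMoments":
        payload = json.loads(Path(path).read_text())
        return cls(
            int(payload["n"]),
            np.asarray(payload["mean"], dtype=float),
            np.asarray(payload["comoment"], dtype=float),
            np.asarray(payload.get("mean_comp", []), dtype=float)
            if payload.get("mean_comp") is not None
            else None,
        )


def line_moments(block: Union[LineBlock, np.ndarray]) -> RunningMoments:
    """Two-pass moments of a single bands x samples line."""
    X = _values(block)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("line must be a bands x samples matrix with >= 1 sample")
    mu0 = X.mean(axis=1)
    # corrected two-pass mean: for data riding on a large offset the first
    # pass loses low-order digits; the residual mean is computed on small
    # centered values and recovers them.  The two-sum error term keeps the
    # recovered bits available to later merges.
    resid = (X - mu0[:, None]).mean(axis=1)
    mu = mu0 + resid
    comp = (mu0 - mu) + resid
    Xc = X - mu[:, None]
    C = Xc @ Xc.T
    return RunningMoments(X.shape[1], mu, 0.5 * (C + C.T), comp)


def merge_moments(prev: RunningMoments, incoming: RunningMoments) -> RunningMoments:
    """Pairwise (Pebay/Chan-style) merge of two moment sets."""
    if prev.bands != incoming.bands:
        raise ValueError(
            f"band count mismatch: {prev.bands} vs {incoming.bands}"
        )
    if prev.n == 0:
        return incoming.copy()
    if incoming.n == 0:
        return prev.copy()
    n = prev.n + incoming.n
    # the leading difference of two nearby means is exact (Sterbenz); the
    # compensation terms restore the sub-ulp bits of each mean
    delta = (incoming.mean - prev.mean) + (incoming._comp() - prev._comp())
    add = (incoming.n / n) * delta + prev._comp()
    mean = prev.mean + add
    comp = (prev.mean - mean) + add  # two-sum error of the mean update
    C = (
        prev.comoment
        + incoming.comoment
        + np.outer(delta, delta) * (prev.n * incoming.n / n)
    )
    return RunningMoments(n, mean, 0.5 * (C + C.T), comp)


def covariance(moments: RunningMoments) -> np.ndarray:
    """Population covariance (co-moment / n)."""
    if moments.n < 1:
        raise ValueError("covariance undefined for empty moments")
    C = moments.comoment / moments.n
    return 0.5 * (C + C.T)


def noise_line(
    block: Union[LineBlock, np.ndarray],
    convention: NoiseConvention = NoiseConvention.INV_SQRT2,
):
    """Pseudo-noise from scaled differences of adjacent samples in one line.

    Returns a bands x (samples-1) block; differences are strictly
    cross-track so the estimate needs only the current line.  Output type
    mirrors the input (LineBlock in, LineBlock out).
    """
    X = _values(block)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("noise estimate needs at least 2 samples per line")
    diff = convention.scale * (X[:, :-1] - X[:, 1:])
    if isinstance(block, LineBlock):
        return LineBlock(block.line_index, diff)
    return diff
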