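"""Run configuration shared by the batch and streaming denoisers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .stats import NoiseConvention

__all__ = ["RetentionPolicy", "DenoiseConfig"]


@dataclass(frozen=True)
class RetentionPolicy:
    """How many high-SNR components to keep in the inverse transform.

    kind:
      * ``fixed``        -- keep exactly ``value`` components
      * ``min_snr``      -- keep the largest r with SNR_{r-1} >= value
      * ``min_fraction`` -- keep the smallest r whose conserved-signal
                            fraction reaches ``value``
      * ``gap``          -- cut at the largest relative jump in the
                            ascending eigenvalue sequence (the visual
                            "eigenvalue plot" criterion, automated)
    """

    kind: str
    value: Optional[float] = None

    _KINDS = ("fixed", "min_snr", "min_fraction", "gap")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown retention policy {self.kind!r}")
        if self.kind == "fixed":
            if self.value is None or int(self.value) != self.value or self.value < 1:
                raise ValueError("fixed policy needs a positive integer r")
        elif self.kind in ("min_snr", "min_fraction"):
            if self.value is None or self.value <= 0:
                raise ValueError(f"{self.kind} policy needs a positive threshold")
        elif self.kind == "gap" and self.value is not None:
            raise ValueError("gap policy takes no value")

    @classmethod
    def fixed(cls, r: int) -> "RetentionPolicy":
        return cls("fixed", int(r))

    @classmethod
    def min_snr(cls, tau: float) -> "RetentionPolicy":
        return cls("min_snr", float(tau))

    @classmethod
    def min_fraction(cls, phi: float) -> "RetentionPolicy":
        return cls("min_fraction", float(phi))

    @classmethod
    def gap(cls) -> "RetentionPolicy":
        return cls("gap")


@dataclass
class DenoiseConfig:
    """Knobs of the (streaming) minimum-noise-fraction denoiser.

    ``eig_cadence`` solves the eigenproblem only every k-th line; lines in
    between reuse the previous denoising matrix.  ``warmup_lines`` lets the
    covariance estimate accumulate before the first solve; warm-up lines
    are passed through unmodified.  ``freeze_after_warmup`` solves exactly
    once (at the end of warm-up) and never again.
    """

    policy: RetentionPolicy = field(default_factory=RetentionPolicy.gap)
    eig_cadence: int = 1
    warmup_lines: int = 0
    freeze_after_warmup: bool = False
    noise_convention: NoiseConvention = NoiseConvention.INV_SQRT2
    reg_eps: float = 1e-10
    emit_zero_meaned: bool = False

    def __post_init__(self) -> None:
        if int(self.eig_cadence) != self.eig_cadence or self.eig_cadence < 1:
            raise ValueError("eig_cadence must be a positive integer")
        if int(self.warmup_lines) != self.warmup_lines or self.warmup_lines < 0:
            raise ValueError("warmup_lines must be a nonnegative integer")
        if self.reg_eps < 0:
            raise ValueError("reg_eps must be nonnegative")
        self.eig_cadence = int(self.eig_cadence)
        self.warmup_lines = int(self.warmup_lines)
        if isinstance(self.noise_convention, str):
            self.noise_convention = NoiseConvention(self.noise_convention)
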