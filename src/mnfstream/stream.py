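"""Line-by-line MNF denoising with incrementally updated statistics.

For each arriving line the image moments are merged with the line's
moments and the noise moments with those of its adjacent-sample
differences; on the configured cadence the generalized eigenproblem is
re-solved on the *current* covariances and the denoising matrix D_i
rebuilt.  The line is then denoised with D_i (statistics update always
precedes denoising, so a line's own pixels inform the matrix applied to
it).  As lines accumulate, {D_i} converges to the matrix conventional
full-image MNF would produce — with cadence 1 and no warm-up the final
line is denoised with exactly the batch matrix.

Lines seen before the warm-up completes, or while the covariance estimate
is still too degenerate for the eigensolve, are passed through unmodified
and flagged; streaming never aborts on a degenerate early solve (it simply
retries at the next cadence tick).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import DenoiseConfig
from .envi import HypercubeHeader, LineBlock
from .mnf import (
    DenoisingMatrix,
    EigensolveError,
    MNFModel,
    apply_denoise,
    choose_r,
    component_table,
    denoising_matrix,
    solve_mnf,
)
from .stats import RunningMoments, covariance, line_moments, merge_moments, noise_line

__all__ = [
    "LineFlag",
    "StreamState",
    "StreamRunReport",
    "init_stream",
    "process_line",
    "finalize",
    "LineByLineDenoiser",
    "denoise_stream",
]


class LineFlag(str, Enum):
    DENOISED = "denoised"
    PASSTHROUGH_WARMUP = "passthrough-warmup"
    PASSTHROUGH_DEGENERATE = "passthrough-degenerate"


@dataclass
class StreamState:
    config: DenoiseConfig
    image_moments: RunningMoments
    noise_moments: RunningMoments
    lines_seen: int = 0
    model: Optional[MNFModel] = None
    dmatrix: Optional[DenoisingMatrix] = None
    flags: List[LineFlag] = field(default_factory=list)
    solves: int = 0
    last_solve_line: Optional[int] = None
    errors: List[str] = field(default_factory=list)


def init_stream(
    config: DenoiseConfig, header: Optional[HypercubeHeader] = None, bands: int = 0
) -> StreamState:
    """Fresh state: empty moments, no model.

    Band count is taken from *header* if given; otherwise it is fixed by
    the first processed line (``bands=0`` sentinel).
    """
    b = header.bands if header is not None else int(bands)
    return StreamState(
        config=config,
        image_moments=RunningMoments.zero(b),
        noise_moments=RunningMoments.zero(b),
    )


def _solve_due(state: StreamState) -> bool:
    cfg = state.config
    i = state.lines_seen  # index of the line currently being processed
    if i < cfg.warmup_lines:
        return False
    if cfg.freeze_after_warmup and state.model is not None:
        return False
    return (i - cfg.warmup_lines) % cfg.eig_cadence == 0


def process_line(
    state: StreamState, block: LineBlock
) -> Tuple[LineBlock, StreamState]:
    """Ingest one line: update moments, maybe re-solve, denoise, flag.

    Mutates and returns *state* along with the output line.  The output is
    per-pixel: D acts on each column of the line independently.
    """
    X = np.asarray(block.values, dtype=float)
    if state.image_moments.bands == 0:
        state.image_moments = RunningMoments.zero(X.shape[0])
        state.noise_moments = RunningMoments.zero(X.shape[0])
    if X.shape[0] != state.image_moments.bands:
        raise ValueError(
            f"line has {X.shape[0]} bands, stream expects {state.image_moments.bands}"
        )

    cfg = state.config
    state.image_moments = merge_moments(state.image_moments, line_moments(X))
    if X.shape[1] >= 2:
        state.noise_moments = merge_moments(
            state.noise_moments,
            line_moments(noise_line(X, cfg.noise_convention)),
        )

    in_warmup = state.lines_seen < cfg.warmup_lines
    if _solve_due(state) and state.noise_moments.n > 0:
        try:
            model = solve_mnf(
                covariance(state.image_moments),
                covariance(state.noise_moments),
                mean=state.image_moments.mean,
                reg_eps=cfg.reg_eps,
            )
            r = choose_r(model, cfg.policy)
            state.dmatrix = denoising_matrix(model, r)
            state.model = model
            state.solves += 1
            state.last_solve_line = state.lines_seen
        except (EigensolveError, ValueError) as exc:
            # degenerate statistics: keep any previous model, retry on the
            # next cadence tick
            state.errors.append(f"line {state.lines_seen}: {exc}")

    state.lines_seen += 1

    if state.model is not None and state.dmatrix is not None:
        mu = state.image_moments.mean  # streaming mean at processing time
        out = apply_denoise(state.dmatrix, X, mu, cfg.emit_zero_meaned)
        flag = LineFlag.DENOISED
    else:
        out = X.copy()
        flag = LineFlag.PASSTHROUGH_WARMUP if in_warmup else LineFlag.PASSTHROUGH_DEGENERATE
    state.flags.append(flag)
    return LineBlock(block.line_index, out), state


@dataclass
class StreamRunReport:
    model: Optional[MNFModel]
    dmatrix: Optional[DenoisingMatrix]
    flags: List[LineFlag]
    lines_seen: int
    solves: int
    last_solve_line: Optional[int]
    warnings: List[str]
    errors: List[str]
    table: Optional[pd.DataFrame]

    @property
    def n_denoised(self) -> int:
        return sum(f is LineFlag.DENOISED for f in self.flags)

    @property
    def n_passthrough(self) -> int:
        return self.lines_seen - self.n_denoised


def finalize(state: StreamState) -> StreamRunReport:
    """Close the stream: final model, per-line flags, eigenvalue/SNR table."""
    warns: List[str] = []
    if state.lines_seen <= state.config.warmup_lines:
        warns.append(
            f"warm-up of {state.config.warmup_lines} lines never completed "
            f"({state.lines_seen} lines seen)"
        )
    table = None
    if state.model is not None:
        table = component_table(
            state.model, None if state.dmatrix is None else state.dmatrix.r
        )
    return StreamRunReport(
        model=state.model,
        dmatrix=state.dmatrix,
        flags=list(state.flags),
        lines_seen=state.lines_seen,
        solves=state.solves,
        last_solve_line=state.last_solve_line,
        warnings=warns,
        errors=list(state.errors),
        table=table,
    )


def save_state(state: StreamState, path) -> None:
    """Persist moments and counters so an interrupted stream can resume.

    The model/denoising matrix are not stored; they are rebuilt from the
    moments at the next cadence tick after resuming.
    """
    import json

    cfg = state.config
    payload = {
        "config": {
            "policy_kind": cfg.policy.kind,
            "policy_value": cfg.policy.value,
            "eig_cadence": cfg.eig_cadence,
            "warmup_lines": cfg.warmup_lines,
            "freeze_after_warmup": cfg.freeze_after_warmup,
            "noise_convention": cfg.noise_convention.value,
            "reg_eps": cfg.reg_eps,
            "emit_zero_meaned": cfg.emit_zero_meaned,
        },
        "lines_seen": state.lines_seen,
        "solves": state.solves,
        "last_solve_line": state.last_solve_line,
        "flags": [f.value for f in state.flags],
        "image": {
            "n": state.image_moments.n,
            "mean": state.image_moments.mean.tolist(),
            "comoment": state.image_moments.comoment.tolist(),
            "mean_comp": state.image_moments._comp().tolist(),
        },
        "noise": {
            "n": state.noise_moments.n,
            "mean": state.noise_moments.mean.tolist(),
            "comoment": state.noise_moments.comoment.tolist(),
            "mean_comp": state.noise_moments._comp().tolist(),
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_state(path) -> StreamState:
    import json

    from .config import RetentionPolicy

    with open(path) as fh:
        payload = json.load(fh)
    c = payload["config"]
    cfg = DenoiseConfig(
        policy=RetentionPolicy(c["policy_kind"], c["policy_value"]),
        eig_cadence=c["eig_cadence"],
        warmup_lines=c["warmup_lines"],
        freeze_after_warmup=c["freeze_after_warmup"],
        noise_convention=c["noise_convention"],
        reg_eps=c["reg_eps"],
        emit_zero_meaned=c["emit_zero_meaned"],
    )

    def _mom(d):
        return RunningMoments(
            int(d["n"]),
            np.asarray(d["mean"], float),
            np.asarray(d["comoment"], float),
            np.asarray(d["mean_comp"], float) if "mean_comp" in d else None,
        )

    return StreamState(
        config=cfg,
        image_moments=_mom(payload["image"]),
        noise_moments=_mom(payload["noise"]),
        lines_seen=int(payload["lines_seen"]),
        solves=int(payload["solves"]),
        last_solve_line=payload["last_solve_line"],
        flags=[LineFlag(f) for f in payload["flags"]],
    )


class LineByLineDenoiser:
    """Pull-based streaming wrapper: push lines in, get denoised lines out."""

    def __init__(
        self, config: Optional[DenoiseConfig] = None, header: Optional[HypercubeHeader] = None
    ):
        self.state = init_stream(config or DenoiseConfig(), header)

    def push(self, block: LineBlock) -> LineBlock:
        out, self.state = process_line(self.state, block)
        return out

    def finalize(self) -> StreamRunReport:
        return finalize(self.state)

    def denoise_cube(self, cube: np.ndarray) -> Tuple[np.ndarray, StreamRunReport]:
        """Stream a ``(lines, samples, bands)`` array line by line."""
        cube = np.asarray(cube, dtype=float)
        L, P, B = cube.shape
        out = np.empty_like(cube)
        for i in range(L):
            out[i] = self.push(LineBlock(i, cube[i].T)).values.T
        return out, self.finalize()


def denoise_stream(
    blocks: Iterable[LineBlock], config: Optional[DenoiseConfig] = None
) -> Iterator[LineBlock]:
    """Generator form: ``stream_lines(...) -> denoise_stream -> write_lines``."""
    state = init_stream(config or DenoiseConfig())
    for block in blocks:
        out, state = process_line(state, block)
        yield out
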