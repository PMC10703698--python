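"""FRAP trace normalization and single-exponential recovery fitting.

A trace is normalized against a background region measured outside the cell:
``I_norm(t) = (I(t) − B(t)) / mean_prebleach(I − B)`` (single normalization;
the prebleach mean of the output is 1 by construction). A single-exponential
recovery

    I(t) = I_inf − (I_inf − I_0) · exp(−k (t − t_bleach))

is then least-squares fitted to the post-bleach frames, with the time origin
at the first post-bleach frame. The mobility readout is the recovery
half-life t_1/2 = ln 2 / k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import ConfigError, IdentifiabilityError, InputError, NormalizationError

__all__ = ["FrapTrace", "FrapFit", "normalize_trace", "fit_recovery", "aggregate_fits"]


@dataclass
class FrapTrace:
    """Intensity timecourse with background and the index of the first
    post-bleach frame (default 10, i.e. ten prebleach frames)."""

    times: np.ndarray  # s, strictly increasing
    intensities: np.ndarray
    background: np.ndarray | float = 0.0
    bleach_index: int = 10
    trace_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ConfigError("times and intensities must have matching length")
        if np.any(np.diff(self.times) <= 0):
            raise ConfigError("times must be strictly increasing")
        if np.ndim(self.background) > 0:
            self.background = np.asarray(self.background, dtype=float)
            if self.background.shape != self.times.shape:
                raise ConfigError("per-frame background must match trace length")
        if not 1 <= self.bleach_index < len(self.times):
            raise ConfigError("bleach_index must leave prebleach and post-bleach frames")


@dataclass
class FrapFit:
    """Fitted recovery parameters; ``half_life = ln2 / rate`` by construction."""

    rate: float  # k, 1/s
    bleach_depth: float  # I_0
    plateau: float  # I_inf
    r_squared: float
    n_frames: int
    trace_id: str = ""
    half_life: float = field(init=False)

    def __post_init__(self) -> None:
        self.half_life = math.log(2) / self.rate


def normalize_trace(trace: FrapTrace) -> FrapTrace:
    """Background-subtract and scale so the prebleach mean equals 1."""
    corrected = trace.intensities - np.asarray(trace.background, dtype=float)
    pre_mean = corrected[: trace.bleach_index].mean()
    if pre_mean <= 0:
        raise NormalizationError(
            f"prebleach mean after background subtraction is {pre_mean:.4g} (must be > 0)"
        )
    return FrapTrace(
        times=trace.times.copy(),
        intensities=corrected / pre_mean,
        background=0.0,
        bleach_index=trace.bleach_index,
        trace_id=trace.trace_id,
    )


def fit_recovery(trace: FrapTrace) -> FrapFit:
    """Fit the single-exponential recovery to the post-bleach frames.

    Initialization: I_0 from the first post-bleach value, I_inf from the mean
    of the final 10% of frames, and k from a log-linear regression of
    (I_inf − I) against time. Raises :class:`IdentifiabilityError` for
    non-recovering traces (fitted k ≤ 0 or I_inf ≤ I_0).
    """
    t = trace.times[trace.bleach_index:] - trace.times[trace.bleach_index]
    y = trace.intensities[trace.bleach_index:]
    if len(y) < 4:
        raise InputError("post-bleach segment must have at least 4 frames")

    i0 = float(y[0])
    tail = max(1, len(y) // 10)
    i_inf = float(y[-tail:].mean())
    # amplitude tolerance guards against float-dust "recovery" in flat traces
    atol = 1e-9 * max(1.0, float(np.abs(y).max()))
    resid0 = i_inf - y
    pos = resid0 > atol
    if i_inf - i0 <= atol or pos.sum() < 2:
        raise IdentifiabilityError(
            f"non-recovering trace {trace.trace_id!r}: I_inf={i_inf:.4g} <= I_0={i0:.4g}"
        )
    slope = np.polyfit(t[pos], np.log(resid0[pos]), 1)[0]
    k0 = max(-slope, 1e-6)

    def model(tt, i0_, iinf_, k_):
        return iinf_ - (iinf_ - i0_) * np.exp(-k_ * tt)

    try:
        popt, _ = curve_fit(model, t, y, p0=(i0, i_inf, k0), maxfev=20000)
    except RuntimeError as exc:
        raise IdentifiabilityError(f"fit failed for trace {trace.trace_id!r}: {exc}") from exc
    i0_f, iinf_f, k_f = (float(v) for v in popt)
    if k_f <= 0 or iinf_f <= i0_f + atol:
        raise IdentifiabilityError(
            f"degenerate fit for trace {trace.trace_id!r}: k={k_f:.4g}, "
            f"I_inf={iinf_f:.4g}, I_0={i0_f:.4g}"
        )
    pred = model(t, *popt)
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return FrapFit(rate=k_f, bleach_depth=i0_f, plateau=iinf_f, r_squared=r2,
                   n_frames=len(y), trace_id=trace.trace_id)


def aggregate_fits(fits: list[FrapFit | None]) -> dict:
    """Mean ± sample sd of per-trace half-lives; ``None`` entries count as failures."""
    ok = [f for f in fits if f is not None]
    if not ok:
        raise InputError("no successful fits to aggregate")
    hl = np.array([f.half_life for f in ok])
    return {
        "n": len(ok),
        "n_failed": len(fits) - len(ok),
        "half_life_mean_s": float(hl.mean()),
        "half_life_sd_s": float(hl.std(ddof=1)) if len(ok) > 1 else None,
    }
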