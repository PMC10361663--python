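"""FRAP normalization and one-phase exponential kinetics.

After photobleaching, the measured ROI signal mixes true binding
turnover with acquisition fade.  Double normalization divides that fade
out against a reference region (here the whole spindle):

    I_norm(t) = [I_ref(t_pre) / I_ref(t)] * [I_roi(t) / I_roi(t_pre)]

so the pre-bleach value is exactly 1.  Full-scale normalization then
rescales a bleached ROI so the first post-bleach frame (t0) is 0 and the
pre-bleach level is 1:

    I_fs(t) = [I_norm(t) - I_norm(t0)] / [1 - I_norm(t0)]

Recovery traces are fitted with a one-phase association
``y = plateau * (1 - exp(-k (t - t0)))`` and decay traces (unbleached
ROIs, double-normalized only) with ``y = plateau + amplitude *
exp(-k (t - t0))``; the half-life is ``ln 2 / k``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from spindleflux import image_prep
from spindleflux.image_prep import RoiTrace
from spindleflux.stack import ImageStack

LN2 = math.log(2)


@dataclass
class NormalizedTrace:
    """Dimensionless ROI trace with the pre-bleach and t0 frames flagged."""

    roi_name: str
    times: np.ndarray
    values: np.ndarray
    t_pre_index: int
    t0_index: int
    normalization: str  # "double" or "double+fullscale"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not 0 <= self.t_pre_index < self.t0_index < len(self.times):
            raise ValueError("need t_pre_index < t0_index within the trace")

    def post_bleach(self) -> tuple[np.ndarray, np.ndarray]:
        """(t - t0, values) restricted to frames from t0 on."""
        i = self.t0_index
        return self.times[i:] - self.times[i], self.values[i:]


@dataclass
class ExpFit:
    """One-phase association/decay fit summary; ``halflife = ln 2 / k``."""

    roi_name: str
    kind: str  # "association" or "decay"
    k: float
    plateau: float
    amplitude: float
    halflife: float
    r_squared: float
    n_points: int
    converged: bool
    quality_ok: bool = True


def double_normalize(roi: RoiTrace, ref: RoiTrace, t_pre_index: int,
                     t0_index: int | None = None) -> NormalizedTrace:
    """Acquisition-fade-corrected trace; equals 1 at the pre-bleach frame.

    Both traces must already be background-subtracted.
    """
    roi_v = roi.background_subtracted()
    ref_v = ref.background_subtracted()
    if t0_index is None:
        t0_index = t_pre_index + 1
    bad = np.flatnonzero(ref_v <= 0)
    if bad.size:
        raise ValueError(f"reference trace non-positive at frame {bad[0]}")
    if roi_v[t_pre_index] <= 0:
        raise ValueError(f"ROI trace non-positive at the pre-bleach frame {t_pre_index}")
    values = (ref_v[t_pre_index] / ref_v) * (roi_v / roi_v[t_pre_index])
    return NormalizedTrace(roi.roi_name, roi.times, values, t_pre_index, t0_index, "double")


def full_scale_normalize(trace: NormalizedTrace,
                         t0_index: int | None = None) -> NormalizedTrace:
    """Rescale a double-normalized trace to 0 at t0 and 1 at pre-bleach level."""
    if trace.normalization != "double":
        raise ValueError("full-scale normalization expects a double-normalized trace")
    if t0_index is None:
        t0_index = trace.t0_index
    v0 = trace.values[t0_index]
    if v0 >= 1:
        raise ValueError(
            f"no bleach depth: value at t0 is {v0:.4f} >= 1 (frame {t0_index})"
        )
    values = (trace.values - v0) / (1.0 - v0)
    return NormalizedTrace(trace.roi_name, trace.times, values, trace.t_pre_index,
                           t0_index, "double+fullscale")


# ---------------------------------------------------------------------------
# fitting


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

K_BOUNDS = (1e-5, 10.0)


def _failed(roi_name: str, kind: str, n: int) -> ExpFit:
    return ExpFit(roi_name, kind, math.nan, math.nan, math.nan, math.nan,
                  0.0, n, converged=False, quality_ok=False)


def fit_one_phase_association(trace: NormalizedTrace, min_points: int = 5,
                              r2_flag: float = 0.8) -> ExpFit:
    """Fit ``y = plateau (1 - exp(-k (t - t0)))`` to the post-bleach frames."""
    t, y = trace.post_bleach()
    if len(t) < min_points:
        raise ValueError(f"need >= {min_points} post-bleach points, got {len(t)}")
    if np.ptp(y) == 0:
        return _failed(trace.roi_name, "association", len(t))
    plateau0 = float(np.mean(y[-3:]))
    k0 = _initial_rate(t, y, y[0], plateau0)
    model = lambda tt, k, plateau: plateau * (1.0 - np.exp(-k * tt))
    try:
        popt, _ = curve_fit(model, t, y, p0=[k0, max(plateau0, 1e-3)],
                            bounds=([K_BOUNDS[0], -10.0], [K_BOUNDS[1], 10.0]),
                            maxfev=10000)
    except RuntimeError:
        return _failed(trace.roi_name, "association", len(t))
    k, plateau = map(float, popt)
    r2 = _r_squared(y, model(t, *popt))
    if plateau <= 0 or not np.isfinite(k):
        return _failed(trace.roi_name, "association", len(t))
    return ExpFit(trace.roi_name, "association", k, plateau, plateau, LN2 / k,
                  r2, len(t), converged=True, quality_ok=r2 >= r2_flag)


def fit_one_phase_decay(trace: NormalizedTrace, min_points: int = 5,
                        r2_flag: float = 0.8) -> ExpFit:
    """Fit ``y = plateau + amplitude exp(-k (t - t0))`` to the post-bleach frames."""
    t, y = trace.post_bleach()
    if len(t) < min_points:
        raise ValueError(f"need >= {min_points} post-bleach points, got {len(t)}")
    if np.ptp(y) == 0:
        return _failed(trace.roi_name, "decay", len(t))
    plateau0 = float(np.mean(y[-3:]))
    amp0 = float(y[0] - plateau0)
    k0 = _initial_rate(t, y, y[0], plateau0)
    model = lambda tt, k, plateau, amp: plateau + amp * np.exp(-k * tt)
    try:
        popt, _ = curve_fit(model, t, y, p0=[k0, plateau0, amp0 if amp0 != 0 else 1e-3],
                            bounds=([K_BOUNDS[0], -10.0, 0.0], [K_BOUNDS[1], 10.0, 10.0]),
                            maxfev=10000)
    except (RuntimeError, ValueError):
        return _failed(trace.roi_name, "decay", len(t))
    k, plateau, amp = map(float, popt)
    r2 = _r_squared(y, model(t, *popt))
    if amp <= 1e-9 or not np.isfinite(k) or k >= K_BOUNDS[1] * 0.999:
        return _failed(trace.roi_name, "decay", len(t))
    return ExpFit(trace.roi_name, "decay", k, plateau, amp, LN2 / k,
                  r2, len(t), converged=True, quality_ok=r2 >= r2_flag)


def _initial_rate(t: np.ndarray, y: np.ndarray, y0: float, plateau: float) -> float:
    """k guess from the time the trace crosses half its terminal change."""
    target = y0 + 0.5 * (plateau - y0)
    if plateau >= y0:
        crossed = np.flatnonzero(y >= target)
    else:
        crossed = np.flatnonzero(y <= target)
    t_half = t[crossed[0]] if crossed.size and t[crossed[0]] > 0 else (t[-1] / 2 or 1.0)
    return float(np.clip(LN2 / t_half, *K_BOUNDS))


# ---------------------------------------------------------------------------
# end-to-end


BLEACHED_ROIS = ("bleached_half", "bleached_pole", "bleached_intermediate",
                 "bleached_chromosome")
UNBLEACHED_ROIS = ("unbleached_half", "unbleached_pole", "unbleached_intermediate",
                   "unbleached_chromosome")


def normalize_traces(traces: list, t_pre_index: int, t0_index: int) -> dict:
    """Double-normalize every ROI against the whole spindle; full-scale the
    bleached ROIs.  Returns ``{roi_name: NormalizedTrace}``."""
    by_name = {tr.roi_name: tr for tr in traces}
    ref = by_name["whole_spindle"]
    out = {}
    for name, tr in by_name.items():
        if name == "whole_spindle":
            continue
        dn = double_normalize(tr, ref, t_pre_index, t0_index)
        if name in BLEACHED_ROIS:
            dn = full_scale_normalize(dn)
        out[name] = dn
    return out


def frap_experiment(stack: ImageStack, bleach_mask: np.ndarray,
                    bleach_frame_index: int,
                    background_roi: np.ndarray | None = None,
                    per_zone: bool = True, register: bool = True,
                    chrom_edges: tuple | None = None) -> pd.DataFrame:
    """Full half-spindle FRAP analysis of one cell.

    Registers the stack, segments the spindle on the pre-bleach
    reference frame, builds the six-zone partition, extracts and
    normalizes ROI traces (reference = whole spindle), and fits
    one-phase association (bleached ROIs, full-scale normalized) or
    decay (unbleached ROIs, double-normalized).  Returns one row per
    ROI: roi, kind, k_per_s, halflife_s, plateau, amplitude, r2,
    n_points, converged, quality_ok.
    """
    if not 1 <= bleach_frame_index < stack.n_frames:
        raise ValueError("bleach_frame_index must leave at least one pre-bleach frame")
    t_pre = bleach_frame_index - 1
    if register:
        stack, _ = register_stack_safe(stack)
    ref_frame = stack.frame(t_pre, "reference")
    mask = image_prep.segment_spindle(ref_frame)
    axis = image_prep.find_axis(mask, ref_frame, stack.pixel_size,
                                chrom_edges=chrom_edges)
    zones = image_prep.compartmentalize(mask, axis, bleach_mask)
    rois = zones.rois()
    if not per_zone:
        rois = {k: rois[k] for k in ("whole_spindle", "bleached_half", "unbleached_half")}
    traces = image_prep.extract_zone_traces(stack, rois, background_roi)
    normalized = normalize_traces(traces, t_pre, bleach_frame_index)

    rows = []
    for name, tr in normalized.items():
        try:
            if name in BLEACHED_ROIS:
                fit = fit_one_phase_association(tr)
            else:
                fit = fit_one_phase_decay(tr)
        except ValueError as exc:
            raise ValueError(f"ROI {name!r}: {exc}") from exc
        rows.append({
            "roi": name, "kind": fit.kind, "k_per_s": fit.k,
            "halflife_s": fit.halflife, "plateau": fit.plateau,
            "amplitude": fit.amplitude, "r2": fit.r_squared,
            "n_points": fit.n_points, "converged": fit.converged,
            "quality_ok": fit.quality_ok,
        })
    return pd.DataFrame(rows).sort_values("roi").reset_index(drop=True)


def register_stack_safe(stack: ImageStack):
    """Registration that tolerates single-frame stacks (identity)."""
    if stack.n_frames < 2:
        return stack, [(0.0, 0.0, 0.0)]
    return image_prep.register_stack(stack)
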