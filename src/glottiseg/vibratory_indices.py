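"""Glottal cycle detection and vibratory quotients (CQ, OQ, SQ, MRGA).

Each glottal cycle runs between consecutive minima of the smoothed glottal
area waveform.  Within a cycle the open phase is the span where the
mid-glottis gap width exceeds a closure threshold; the aperture maximum
splits it into an opening and a closing part:

    OQ   = open duration / cycle duration
    CQ   = closing duration / cycle duration
    SQ   = opening duration / closing duration
    MRGA = min area / max area over the cycle

With these phase conventions the per-cycle identity SQ = (OQ - CQ) / CQ
holds exactly; it is used as an internal consistency check of reported
index triples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .acoustic_processing import amplitude_spectrum
from .errors import InsufficientCyclesError, ParameterError
from .glottal_geometry import GlottalAreaWaveform, GlottalGapWaveform

log = logging.getLogger(__name__)

DEFAULT_CLOSURE_EPS_PX = 0.5


@dataclass(frozen=True)
class Cycle:
    """One glottal cycle, all bounds half-open frame indices."""

    start: int
    end: int
    open_start: int
    open_end: int
    max_aperture_frame: int

    @property
    def n_frames(self) -> int:
        return self.end - self.start

    @property
    def opens(self) -> bool:
        return self.open_end > self.open_start


@dataclass(frozen=True)
class CycleSet:
    """Ordered, non-overlapping glottal cycles plus the period estimate."""

    cycles: tuple[Cycle, ...]
    dominant_period_frames: float
    closure_eps: float = DEFAULT_CLOSURE_EPS_PX


@dataclass(frozen=True)
class GlottalIndices:
    """Per-recording vibratory quotients, averaged over detected cycles."""

    CQ: float
    OQ: float
    SQ: float
    MRGA: float
    n_cycles: int

    def rounded(self, ndigits: int = 2) -> "GlottalIndices":
        return GlottalIndices(
            round(self.CQ, ndigits),
            round(self.OQ, ndigits),
            round(self.SQ, ndigits),
            round(self.MRGA, ndigits),
            self.n_cycles,
        )


def dominant_period(series: np.ndarray) -> float:
    """Period (frames) of the strongest non-DC spectral component."""
    x = np.asarray(series, dtype=np.float64)
    spec = amplitude_spectrum(x - x.mean())
    k = spec.dominant_bin(skip_dc=True)
    if spec.moduli[k] <= 0:
        raise InsufficientCyclesError("series has no oscillatory component")
    return x.size / k


def detect_cycles(
    gaw: GlottalAreaWaveform,
    ggw: GlottalGapWaveform,
    smooth_window: int | None = None,
    closure_eps: float = DEFAULT_CLOSURE_EPS_PX,
) -> CycleSet:
    """Delimit glottal cycles at consecutive minima of the smoothed GAW.

    Minima must be at least half the dominant period apart (the period is
    read from the GAW spectrum peak).  ``smooth_window`` defaults to one
    eighth of that period and is forced odd so smoothing stays centred.
    Open frames are those where the mid-level gap width exceeds
    ``closure_eps``.  The aperture maximum is the argmax of the gap width
    within the cycle; the gap width is an integer-quantized rasterized
    quantity, so plateaus at the maximum are common and ties are resolved
    by the largest glottal area, then by the earliest frame.
    """
    area = gaw.area
    width = ggw.width
    if area.size != width.size:
        raise ParameterError("GAW and GGW lengths differ")
    if np.ptp(area) == 0:
        raise InsufficientCyclesError("constant glottal area: no oscillation")

    period = dominant_period(area)
    if smooth_window is None:
        smooth_window = max(int(period // 8), 1)
    if smooth_window < 1:
        raise ParameterError("smooth_window must be >= 1")
    if smooth_window % 2 == 0:
        smooth_window += 1  # keep the moving average centred
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(area, kernel, mode="same")

    distance = max(int(0.5 * period), 1)
    minima, _ = sp_signal.find_peaks(-smoothed, distance=distance)
    if minima.size < 3:
        raise InsufficientCyclesError(
            f"found {max(minima.size - 1, 0)} cycles; need at least 2"
        )

    cycles = []
    for a, b in zip(minima[:-1], minima[1:]):
        a, b = int(a), int(b)
        open_idx = np.flatnonzero(width[a:b] > closure_eps)
        if open_idx.size:
            open_start = a + int(open_idx[0])
            open_end = a + int(open_idx[-1]) + 1
            w_open = width[open_start:open_end]
            at_max = np.flatnonzero(w_open == w_open.max())
            if at_max.size > 1:
                a_open = area[open_start:open_end][at_max]
                at_max = at_max[a_open == a_open.max()]
            m = open_start + int(at_max[0])
        else:
            open_start = open_end = m = a
        cycles.append(Cycle(a, b, open_start, open_end, m))
    return CycleSet(tuple(cycles), period, closure_eps)


def _refined_phases(
    cyc: Cycle, width: np.ndarray, eps: float
) -> tuple[float, float, float]:
    """Sub-frame (open_start, aperture_max, open_end) for one cycle.

    The closure-threshold crossings are linearly interpolated between the
    neighbouring samples, and the aperture maximum is the centre of mass
    of the above-threshold width excess over the open span.  Rasterized
    gap widths move in whole-pixel steps, so without this refinement
    every phase boundary carries up to one frame of quantization error,
    which is large relative to a 20-frame cycle; the centre of mass
    integrates over the pulse and cancels the first-order error (at the
    cost of a small bias toward the pulse centre for skewed pulses).
    """
    t0 = float(cyc.open_start)
    if cyc.open_start > cyc.start:
        w_prev = width[cyc.open_start - 1]
        w_here = width[cyc.open_start]
        if w_here > w_prev:
            t0 = cyc.open_start - 1 + (eps - w_prev) / (w_here - w_prev)
    t1 = float(cyc.open_end)
    if cyc.open_end < cyc.end:
        w_last = width[cyc.open_end - 1]
        w_next = width[cyc.open_end]
        if w_last > w_next:
            t1 = cyc.open_end - 1 + (w_last - eps) / (w_last - w_next)
    w_open = width[cyc.open_start : cyc.open_end]
    excess = np.maximum(w_open - eps, 0.0)
    t_rel = np.arange(cyc.open_start, cyc.open_end, dtype=float)
    if excess.sum() > 0:
        m = float(np.clip((t_rel * excess).sum() / excess.sum(), t0, t1))
    else:
        m = float(cyc.max_aperture_frame)
    return t0, m, t1


def compute_indices(
    cycles: CycleSet,
    ggw_mid: GlottalGapWaveform,
    gaw: GlottalAreaWaveform,
    aggregate: str = "mean",
    subframe: bool = True,
) -> GlottalIndices:
    """Average the per-cycle quotients into one set of recording indices.

    With ``subframe=True`` (default) the phase boundaries are refined to
    sub-frame precision before the quotients are formed; ``False`` keeps
    the whole-frame boundaries recorded in the cycle set.  Cycles with
    zero maximum area are skipped with a warning; SQ is averaged only
    over cycles with a non-empty closing phase and is an error when no
    cycle has one.
    """
    if len(cycles.cycles) < 2:
        raise InsufficientCyclesError("need at least 2 cycles")
    if aggregate not in ("mean", "median"):
        raise ParameterError("aggregate must be 'mean' or 'median'")
    agg = np.mean if aggregate == "mean" else np.median

    oq, cq, sq, mrga = [], [], [], []
    skipped = 0
    for cyc in cycles.cycles:
        area = gaw.area[cyc.start : cyc.end]
        amax = area.max()
        if amax <= 0:
            skipped += 1
            continue
        T = cyc.n_frames
        if cyc.opens and subframe:
            t0, m, t1 = _refined_phases(cyc, ggw_mid.width, cycles.closure_eps)
        else:
            t0, m, t1 = (
                float(cyc.open_start),
                float(cyc.max_aperture_frame),
                float(cyc.open_end),
            )
        oq.append((t1 - t0) / T)
        closing = t1 - m
        opening = m - t0
        cq.append(closing / T)
        if closing > 0:
            sq.append(opening / closing)
        mrga.append(area.min() / amax)
    if skipped:
        log.warning("skipped %d cycles with zero maximum area", skipped)
    if not oq:
        raise InsufficientCyclesError("every cycle had zero maximum area")
    if not sq:
        raise InsufficientCyclesError(
            "SQ undefined: closing phase empty in every cycle"
        )
    return GlottalIndices(
        CQ=float(agg(cq)),
        OQ=float(agg(oq)),
        SQ=float(agg(sq)),
        MRGA=float(agg(mrga)),
        n_cycles=len(oq),
    )


def consistency_check(indices: GlottalIndices) -> float:
    """Residual of the phase identity SQ = (OQ - CQ) / CQ."""
    if indices.CQ <= 0:
        raise ParameterError("CQ must be positive for the identity check")
    return abs(indices.SQ - (indices.OQ - indices.CQ) / indices.CQ)


def identity_interval(
    cq: float, oq: float, rounding: float = 0.005
) -> tuple[float, float]:
    """Range of (OQ - CQ) / CQ over the +/-``rounding`` boxes around CQ, OQ.

    Printed two-decimal CQ and OQ values stand for any true values within
    half a unit of the last digit; the identity residual of a printed SQ
    must be judged against the whole induced interval.
    """
    cq_lo, cq_hi = cq - rounding, cq + rounding
    oq_lo, oq_hi = oq - rounding, oq + rounding
    if cq_lo <= 0:
        raise ParameterError("CQ rounding interval must stay positive")
    # (oq - cq)/cq is increasing in oq and decreasing in cq
    return (oq_lo - cq_hi) / cq_hi, (oq_hi - cq_lo) / cq_lo
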