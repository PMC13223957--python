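"""Calcium-trace processing and the weighted mean response (WMR) size-tuning
statistic.

The pipeline goes: raw ROI fluorescence -> ΔF/F against the pre-session
baseline -> 3-point sliding-median smoothing -> responsiveness gate
(max ΔF/F >= 0.5) -> per-size repetition- and time-averaged responses ->
WMR angle.  The WMR angle is the response-weighted geometric mean of the
presented angular sizes,

    log10(WMR) = sum_i w_i * log10(x_i),    w_i = r_i / sum_j r_j,

with r_i the mean ΔF/F during the stimulus phases of size x_i (negative
means clamped to zero before normalization).  It summarizes a neuron's size
tuning as a single preferred angle lying between the smallest and largest
presented size.  Population tuning is compared through cumulative WMR
distributions, their medians, and anterior/medial/posterior groupings along
the tectal A-P axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (AlignmentError, ConfigurationError,
                     DegenerateBaselineError, UndefinedShiftError,
                     UndefinedWmrError)
from .protocol import StimulusProtocol

Region = Literal["anterior", "medial", "posterior"]

RESPONSIVENESS_THRESHOLD = 0.5
SMALL_SIZE_MAX_DEG = 5.0
LARGE_SIZE_MIN_DEG = 10.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RoiRecord:
    """One neuron's identity: ROI id, centroid (x right, y down, 0-based
    pixels), and the summed-pixel fluorescence time series."""

    roi_id: int
    centroid_xy: tuple[float, float]
    raw_f: np.ndarray

    def __post_init__(self) -> None:
        self.raw_f = np.asarray(self.raw_f, dtype=float)
        if not np.all(np.isfinite(self.raw_f)):
            raise ValueError(f"ROI {self.roi_id}: raw_f must be finite")


@dataclass
class DffTrace:
    roi_id: int
    dff: np.ndarray
    smoothed: bool = False


@dataclass
class SizeTuningProfile:
    """Per-size repetition-averaged, time-averaged ΔF/F for one neuron."""

    roi_id: int
    sizes_deg: np.ndarray
    mean_response: np.ndarray
    responsive: bool

    def __post_init__(self) -> None:
        self.sizes_deg = np.asarray(self.sizes_deg, dtype=float)
        self.mean_response = np.asarray(self.mean_response, dtype=float)
        if self.sizes_deg.shape != self.mean_response.shape:
            raise ValueError("sizes and responses must have equal length")
        if np.any(np.diff(self.sizes_deg) <= 0) or np.any(self.sizes_deg <= 0):
            raise ValueError("sizes must be strictly increasing and positive")


@dataclass
class WmrRecord:
    roi_id: int
    wmr_angle_deg: float
    ap_scale: float
    ap_region: Region


@dataclass
class CumulativeWmrCurve:
    """Empirical cumulative WMR distribution in percent (0, 100]."""

    angles_deg: np.ndarray
    cumulative_pct: np.ndarray


# ---------------------------------------------------------------------------
# registration & extraction
# ---------------------------------------------------------------------------

def phase_correlation_shift(frame: np.ndarray,
                            reference: np.ndarray) -> tuple[int, int]:
    """Integer (dx, dy) translation aligning ``frame`` to ``reference``.

    Maximizes the inverse FFT of the unit-normalized cross-power spectrum
    (phase correlation).  Rolling ``frame`` by ``dy`` rows and ``dx`` columns
    registers it onto ``reference``; re-estimating after applying the shift
    returns (0, 0).
    """
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape != reference.shape or frame.ndim != 2:
        raise ConfigurationError("frame and reference must be equal-shape 2-D")
    if np.ptp(frame) == 0 or np.ptp(reference) == 0:
        raise UndefinedShiftError("constant image: shift is undefined")
    spectrum = np.fft.fft2(reference) * np.conj(np.fft.fft2(frame))
    magnitude = np.abs(spectrum)
    magnitude[magnitude == 0] = 1.0
    surface = np.real(np.fft.ifft2(spectrum / magnitude))
    dy, dx = np.unravel_index(np.argmax(surface), surface.shape)
    ny, nx = surface.shape
    if dy > ny // 2:
        dy -= ny
    if dx > nx // 2:
        dx -= nx
    return int(dx), int(dy)


def extract_roi_trace(stack: np.ndarray, mask: np.ndarray,
                      roi_id: int) -> RoiRecord:
    """Summed-pixel fluorescence of one labeled ROI across all frames."""
    stack = np.asarray(stack, dtype=float)
    mask = np.asarray(mask)
    if stack.ndim != 3 or stack.shape[1:] != mask.shape:
        raise ConfigurationError("stack frames and mask shapes must agree")
    member = mask == roi_id
    if not member.any():
        raise KeyError(f"roi_id {roi_id} not present in mask")
    raw_f = stack[:, member].sum(axis=1)
    ys, xs = np.nonzero(member)
    centroid = (float(xs.mean()), float(ys.mean()))
    return RoiRecord(roi_id=int(roi_id), centroid_xy=centroid, raw_f=raw_f)


# ---------------------------------------------------------------------------
# trace processing
# ---------------------------------------------------------------------------

def compute_dff(record: RoiRecord, protocol: StimulusProtocol) -> DffTrace:
    """ΔF/F = (F_t - F0)/F0 with F0 the mean over the pre-session frames."""
    raw = record.raw_f
    if raw.size != protocol.n_frames:
        raise AlignmentError(
            f"trace length {raw.size} != protocol frames {protocol.n_frames}")
    if protocol.pre_frames < 1:
        raise ConfigurationError("protocol has no pre-session baseline frames")
    f0 = float(raw[list(protocol.baseline_frames)].mean())
    if f0 <= 0:
        raise DegenerateBaselineError(
            f"ROI {record.roi_id}: baseline F0={f0} is not positive")
    return DffTrace(roi_id=record.roi_id, dff=(raw - f0) / f0, smoothed=False)


def smooth_median3(trace: DffTrace) -> DffTrace:
    """3-point sliding median; truncated 2-point window at both ends.

    Removes single-frame noise spikes without distorting the 18-frame
    stimulus-phase plateaus.
    """
    x = trace.dff
    if x.size == 0:
        raise ValueError("empty trace")
    out = x.astype(float).copy()
    if x.size >= 3:
        stacked = np.stack([x[:-2], x[1:-1], x[2:]])
        out[1:-1] = np.median(stacked, axis=0)
    if x.size >= 2:
        out[0] = np.median(x[:2])
        out[-1] = np.median(x[-2:])
    return DffTrace(roi_id=trace.roi_id, dff=out, smoothed=True)


def is_responsive(trace: DffTrace,
                  threshold: float = RESPONSIVENESS_THRESHOLD) -> bool:
    """True iff the trace reaches ΔF/F >= threshold at any frame (inclusive)."""
    return bool(np.max(trace.dff) >= threshold)


def size_responses(trace: DffTrace,
                   protocol: StimulusProtocol,
                   threshold: float = RESPONSIVENESS_THRESHOLD,
                   ) -> SizeTuningProfile:
    """Repetition-averaged, time-averaged ΔF/F within each size's stimulus
    phases (both sweep directions pooled)."""
    if trace.dff.size != protocol.n_frames:
        raise AlignmentError(
            f"trace length {trace.dff.size} != protocol frames "
            f"{protocol.n_frames}")
    responses = []
    for size in protocol.sizes_deg:
        windows = protocol.stim_windows(size)
        per_rep = [float(trace.dff[start:stop].mean())
                   for start, stop in windows]
        responses.append(float(np.mean(per_rep)))
    return SizeTuningProfile(
        roi_id=trace.roi_id,
        sizes_deg=np.asarray(protocol.sizes_deg, dtype=float),
        mean_response=np.asarray(responses, dtype=float),
        responsive=is_responsive(trace, threshold))


# ---------------------------------------------------------------------------
# the WMR statistic
# ---------------------------------------------------------------------------

def wmr_angle(profile: SizeTuningProfile) -> float:
    """Weighted mean response angle in degrees.

    Negative mean responses are clamped to zero before the weights are
    normalized; a neuron with no positive response has no defined WMR and
    raises :class:`UndefinedWmrError` so callers exclude it explicitly.
    """
    clamped = np.maximum(profile.mean_response, 0.0)
    total = clamped.sum()
    if total <= 0:
        raise UndefinedWmrError(
            f"ROI {profile.roi_id}: all size responses are non-positive")
    weights = clamped / total
    return float(10.0 ** np.dot(weights, np.log10(profile.sizes_deg)))


def cumulative_wmr(wmrs: Sequence[WmrRecord] | np.ndarray
                   ) -> CumulativeWmrCurve:
    """Empirical cumulative frequency distribution of WMR angles, in percent."""
    angles = np.asarray(
        [w.wmr_angle_deg if isinstance(w, WmrRecord) else float(w)
         for w in wmrs], dtype=float)
    if angles.size == 0:
        raise ValueError("cumulative distribution of an empty WMR set")
    order = np.sort(angles)
    pct = 100.0 * np.arange(1, order.size + 1) / order.size
    return CumulativeWmrCurve(angles_deg=order, cumulative_pct=pct)


def median_wmr(curve: CumulativeWmrCurve | Sequence[WmrRecord] | np.ndarray
               ) -> float:
    """Median WMR angle: the angle at which 50% of neurons are responsive.

    Computed as the 50th percentile of the WMR distribution with linear
    interpolation in log10-size space (so the two-point case returns the
    geometric midpoint).
    """
    if not isinstance(curve, CumulativeWmrCurve):
        curve = cumulative_wmr(curve)
    return float(10.0 ** np.median(np.log10(curve.angles_deg)))


# ---------------------------------------------------------------------------
# anterior-posterior topography
# ---------------------------------------------------------------------------

def assign_ap_region(centroid_xy: tuple[float, float],
                     ap_axis: tuple[tuple[float, float], tuple[float, float]],
                     ) -> tuple[float, Region]:
    """Map a centroid onto the 1-10 scale along the tectal diagonal.

    The scale is 1 + 9 * (normalized scalar projection onto the oriented
    axis, clipped to [0, 1]).  Bins: anterior [1, 3], medial (3, 6],
    posterior (6, 10]; boundary values fall into the lower bin.
    """
    (x1, y1), (x2, y2) = ap_axis
    axis = np.array([x2 - x1, y2 - y1], dtype=float)
    length_sq = float(axis @ axis)
    if length_sq == 0:
        raise ConfigurationError("A-P axis has zero length")
    rel = np.array([centroid_xy[0] - x1, centroid_xy[1] - y1], dtype=float)
    frac = float(np.clip((rel @ axis) / length_sq, 0.0, 1.0))
    scale = 1.0 + 9.0 * frac
    if scale <= 3.0:
        region: Region = "anterior"
    elif scale <= 6.0:
        region = "medial"
    else:
        region = "posterior"
    return scale, region


def delta_wmr(pre_records: Iterable[WmrRecord],
              post_records: Iterable[WmrRecord],
              by_region: Sequence[Region] = ("anterior", "medial",
                                             "posterior"),
              ) -> dict[Region, float]:
    """Per-region |mean WMR_post - mean WMR_pre|.

    A region empty in either session maps to NaN (missing-region flag)
    rather than raising.
    """
    def region_means(records: Iterable[WmrRecord]) -> dict[str, float]:
        by: dict[str, list[float]] = {}
        for rec in records:
            by.setdefault(rec.ap_region, []).append(rec.wmr_angle_deg)
        return {r: float(np.mean(v)) for r, v in by.items()}

    pre_means = region_means(pre_records)
    post_means = region_means(post_records)
    out: dict[Region, float] = {}
    for region in by_region:
        if region in pre_means and region in post_means:
            out[region] = abs(post_means[region] - pre_means[region])
        else:
            out[region] = float("nan")
    return out


def count_size_classes(profiles: Iterable[SizeTuningProfile],
                       small_max_deg: float = SMALL_SIZE_MAX_DEG,
                       large_min_deg: float = LARGE_SIZE_MIN_DEG,
                       ) -> dict[str, float]:
    """Count responsive cells preferring small (<= 5°) vs large (>= 10°) sizes.

    Preference is the argmax-response size.  Returns counts and fractions of
    the total responsive population.
    """
    n_small = n_large = n_total = 0
    for profile in profiles:
        if not profile.responsive:
            continue
        n_total += 1
        best = float(profile.sizes_deg[int(np.argmax(profile.mean_response))])
        if best <= small_max_deg:
            n_small += 1
        elif best >= large_min_deg:
            n_large += 1
    frac_small = n_small / n_total if n_total else 0.0
    frac_large = n_large / n_total if n_total else 0.0
    return {"n_small": n_small, "n_large": n_large, "n_responsive": n_total,
            "frac_small": frac_small, "frac_large": frac_large}


# ---------------------------------------------------------------------------
# session-level pipeline
# ---------------------------------------------------------------------------

def analyze_session(records: Sequence[RoiRecord],
                    protocol: StimulusProtocol,
                    ap_axis: tuple[tuple[float, float],
                                   tuple[float, float]] | None = None,
                    threshold: float = RESPONSIVENESS_THRESHOLD,
                    smooth: bool = True) -> pd.DataFrame:
    """Run the full per-neuron pipeline over one session.

    Returns one row per ROI: centroid, A-P scale/region (if an axis is
    given), responsiveness, per-size mean responses, and the WMR angle (NaN
    where undefined or the neuron failed the responsiveness gate).
    """
    rows = []
    for record in records:
        trace = compute_dff(record, protocol)
        if smooth:
            trace = smooth_median3(trace)
        profile = size_responses(trace, protocol, threshold)
        row: dict[str, object] = {
            "roi_id": record.roi_id,
            "x": record.centroid_xy[0],
            "y": record.centroid_xy[1],
            "responsive": profile.responsive,
        }
        if ap_axis is not None:
            scale, region = assign_ap_region(record.centroid_xy, ap_axis)
            row["ap_scale"] = scale
            row["region"] = region
        for size, resp in zip(profile.sizes_deg, profile.mean_response):
            row[f"r_{size:g}"] = resp
        if profile.responsive:
            try:
                row["wmr_deg"] = wmr_angle(profile)
            except UndefinedWmrError:
                row["wmr_deg"] = float("nan")
        else:
            row["wmr_deg"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def session_wmr_records(session_df: pd.DataFrame) -> list[WmrRecord]:
    """WmrRecord list for the responsive, WMR-defined neurons of a session."""
    ok = session_df.dropna(subset=["wmr_deg"])
    return [WmrRecord(roi_id=int(r.roi_id), wmr_angle_deg=float(r.wmr_deg),
                      ap_scale=float(getattr(r, "ap_scale", float("nan"))),
                      ap_region=getattr(r, "region", "medial"))
            for r in ok.itertuples()]
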