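"""Scoring and summary statistics for the size-discrimination and prey assays.

A freely swimming larva interacts with moving dots of different angular
sizes; every encounter is scored approach / avoidance / neutral.  Per larva
and size the module computes

* valence index   (A - V) / (A + V)            in [-1, 1]
* activity index  (A + V) / (A + V + N)        in [0, 1]
* approach / avoidance / neutral probabilities (counts over total)

plus the slow/fast split of avoidance swims by peak velocity, and the
prey-assay metrics (uptake percentage, exposure-normalized avoidance rate).
Undefined indices (zero denominators) are flagged as missing, never raised,
and excluded pairwise from group statistics.  The larva is the statistical
unit throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidSegmentError

Label = Literal["approach", "avoidance", "neutral"]

LABELS: tuple[Label, ...] = ("approach", "avoidance", "neutral")


@dataclass
class InteractionEvent:
    """One larva-stimulus encounter."""

    event_id: int
    size_deg: float
    label: Label
    velocity_mm_s: float | None = None
    distance_mm: float | None = None
    larva_id: int | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.size_deg <= 0:
            raise ValueError("size_deg must be positive")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class TrackSegment:
    """Time-stamped larva and dot centroid positions (mm) during one
    encounter window, sampled at the 35 fps video rate."""

    t: np.ndarray
    larva_xy: np.ndarray
    dot_xy: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.larva_xy = np.asarray(self.larva_xy, dtype=float)
        self.dot_xy = np.asarray(self.dot_xy, dtype=float)
        if self.t.size < 2:
            raise InvalidSegmentError("segment needs at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise InvalidSegmentError("timestamps must be strictly increasing")
        if self.larva_xy.shape != (self.t.size, 2) or \
                self.dot_xy.shape != (self.t.size, 2):
            raise InvalidSegmentError("positions must be (n, 2) arrays")


@dataclass
class ClassificationConfig:
    """Geometric scoring conventions (not printed in any source protocol).

    ``encounter_radius_mm``: dot-larva distance opening an event window.
    ``min_displacement_mm``: net radial displacement required to call a
    directed response.  ``v_threshold_mm_s``: slow/fast avoidance boundary
    (half-open: velocity >= threshold is fast).
    """

    encounter_radius_mm: float = 5.0
    min_displacement_mm: float = 1.0
    v_threshold_mm_s: float = 20.0


@dataclass
class BehaviorSummary:
    """Counts and indices for one larva at one stimulus size.

    Index fields are ``None`` when their denominator is zero.
    """

    size_deg: float
    n_approach: int
    n_avoid: int
    n_neutral: int
    valence_index: float | None = field(init=False)
    activity_index: float | None = field(init=False)
    p_approach: float | None = field(init=False)
    p_avoid: float | None = field(init=False)
    p_neutral: float | None = field(init=False)

    def __post_init__(self) -> None:
        self.valence_index = valence_index(self.n_approach, self.n_avoid)
        self.activity_index = activity_index(
            self.n_approach, self.n_avoid, self.n_neutral)
        probs = interaction_probabilities(
            self.n_approach, self.n_avoid, self.n_neutral)
        self.p_approach, self.p_avoid, self.p_neutral = probs


# ---------------------------------------------------------------------------
# event classification
# ---------------------------------------------------------------------------

def classify_interaction(seg: TrackSegment,
                         cfg: ClassificationConfig | None = None) -> Label:
    """Score one encounter from centroid tracks.

    Approach / avoidance when the net radial displacement of the larva
    toward / away from the dot is at least ``min_displacement_mm``; neutral
    otherwise.  Invariant to rigid transforms of the arena frame.
    """
    cfg = cfg or ClassificationConfig()
    radial = np.linalg.norm(seg.larva_xy - seg.dot_xy, axis=1)
    net_toward = float(radial[0] - radial[-1])
    if net_toward >= cfg.min_displacement_mm:
        return "approach"
    if -net_toward >= cfg.min_displacement_mm:
        return "avoidance"
    return "neutral"


def classify_avoidance_speed(event: InteractionEvent,
                             v_threshold: float = 20.0
                             ) -> Literal["slow", "fast"]:
    """Slow vs fast (escape-like) avoidance by peak swim velocity.

    Half-open boundary: velocity >= threshold is fast.
    """
    if event.label != "avoidance":
        raise ValueError("speed classification applies to avoidance events")
    if event.velocity_mm_s is None:
        raise ValueError("avoidance event lacks a velocity")
    return "slow" if event.velocity_mm_s < v_threshold else "fast"


# ---------------------------------------------------------------------------
# indices
# ---------------------------------------------------------------------------

def valence_index(n_approach: int, n_avoid: int) -> float | None:
    """(A - V)/(A + V); None (missing) when A + V = 0."""
    _check_counts(n_approach, n_avoid)
    total = n_approach + n_avoid
    if total == 0:
        return None
    return (n_approach - n_avoid) / total


def activity_index(n_approach: int, n_avoid: int,
                   n_neutral: int) -> float | None:
    """(A + V)/(A + V + N); None when no events at all."""
    _check_counts(n_approach, n_avoid, n_neutral)
    total = n_approach + n_avoid + n_neutral
    if total == 0:
        return None
    return (n_approach + n_avoid) / total


def interaction_probabilities(n_approach: int, n_avoid: int, n_neutral: int
                              ) -> tuple[float | None, float | None,
                                         float | None]:
    """(p_approach, p_avoid, p_neutral); all None when no events."""
    _check_counts(n_approach, n_avoid, n_neutral)
    total = n_approach + n_avoid + n_neutral
    if total == 0:
        return None, None, None
    return n_approach / total, n_avoid / total, n_neutral / total


def uptake_percentage(n_uptakes: int, n_prey: int) -> float | None:
    """Successful prey uptakes as a percentage of total prey count."""
    _check_counts(n_uptakes, n_prey)
    if n_prey == 0:
        return None
    if n_uptakes > n_prey:
        raise ValueError("uptakes cannot exceed prey count")
    return 100.0 * n_uptakes / n_prey


def avoidance_per_exposure(n_avoidances: int,
                           exposure_units: float) -> float | None:
    """Avoidance events per unit prey exposure, scaled by 100.

    Exposure is defined as (number of prey present x minutes observed).
    """
    _check_counts(n_avoidances)
    if exposure_units < 0:
        raise ValueError("exposure must be nonnegative")
    if exposure_units == 0:
        return None
    return 100.0 * n_avoidances / exposure_units


def _check_counts(*counts: float) -> None:
    for c in counts:
        if not math.isfinite(c) or c < 0:
            raise ValueError("counts must be finite and nonnegative")


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def summarize_behavior(events: Iterable[InteractionEvent],
                       sizes_deg: Sequence[float] | None = None,
                       ) -> dict[float, BehaviorSummary]:
    """Per-size counts and indices for one larva's event list.

    ``sizes_deg`` fixes the summarized size set (sizes with no events get
    all-zero counts and undefined indices); by default the sizes present in
    the events are used.  Order-invariant.
    """
    events = list(events)
    sizes = (sorted({e.size_deg for e in events})
             if sizes_deg is None else [float(s) for s in sizes_deg])
    out: dict[float, BehaviorSummary] = {}
    for size in sizes:
        counts = {label: 0 for label in LABELS}
        for e in events:
            if e.size_deg == size:
                counts[e.label] += 1
        out[size] = BehaviorSummary(
            size_deg=size, n_approach=counts["approach"],
            n_avoid=counts["avoidance"], n_neutral=counts["neutral"])
    return out


def events_to_frame(events: Iterable[InteractionEvent]) -> pd.DataFrame:
    """Flat event table (event_id, larva_id, condition, size_deg, label,
    velocity_mm_s, distance_mm)."""
    return pd.DataFrame(
        [{"event_id": e.event_id, "larva_id": e.larva_id,
          "condition": e.condition, "size_deg": e.size_deg, "label": e.label,
          "velocity_mm_s": e.velocity_mm_s, "distance_mm": e.distance_mm}
         for e in events])


def per_larva_summary(events_df: pd.DataFrame) -> pd.DataFrame:
    """Per-larva per-size index table from a flat event frame.

    Undefined indices propagate as NaN and are excluded pairwise downstream.
    """
    rows = []
    for (larva, condition, size), grp in events_df.groupby(
            ["larva_id", "condition", "size_deg"], dropna=False):
        counts = grp["label"].value_counts()
        summary = BehaviorSummary(
            size_deg=float(size),
            n_approach=int(counts.get("approach", 0)),
            n_avoid=int(counts.get("avoidance", 0)),
            n_neutral=int(counts.get("neutral", 0)))
        rows.append({
            "larva_id": larva, "condition": condition, "size_deg": float(size),
            "n_approach": summary.n_approach, "n_avoid": summary.n_avoid,
            "n_neutral": summary.n_neutral,
            "valence_index": _nan(summary.valence_index),
            "activity_index": _nan(summary.activity_index),
            "p_approach": _nan(summary.p_approach),
            "p_avoid": _nan(summary.p_avoid),
            "p_neutral": _nan(summary.p_neutral),
        })
    return pd.DataFrame(rows)


def group_means(per_larva: pd.DataFrame,
                value: str = "valence_index") -> pd.DataFrame:
    """Mean +/- SEM of one index per condition and size (larvae as units)."""
    def sem(x: pd.Series) -> float:
        x = x.dropna()
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan

    grouped = per_larva.groupby(["condition", "size_deg"])[value]
    out = grouped.agg(mean="mean", sem=sem, n="count").reset_index()
    return out


def _nan(x: float | None) -> float:
    return float("nan") if x is None else float(x)
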