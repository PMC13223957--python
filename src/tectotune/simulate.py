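"""Synthetic data generators for every pipeline input.

The generators stand in for the study's raw recordings so all downstream
stages are testable end to end:

* ``simulate_imaging_session`` — a forward model of size-tuned tectal
  neurons: each neuron has a Gaussian tuning curve in log10 angular size,
  drives a fluorescence trace with first-order calcium rise/decay kinetics,
  and sits at a ground-truth anterior-posterior position.  Feeding state and
  pharmacology enter as an additive log10 shift of preferred size
  (satiety / MTII-like) and an attenuation of small-size-preferring
  responses (dominant-negative receptor-like).  A negative A-P gradient
  makes posterior neurons prefer smaller sizes.
* ``render_stack`` — rasterizes traces into a TIFF-like image stack plus an
  ROI label mask so extraction can be tested as a round trip.
* ``simulate_behavior_session`` — per-size categorical draws of
  approach/avoid/neutral encounters with condition-dependent probability
  tables and a velocity mixture in which slow avoidance swims dominate at
  small stimulus sizes.
* ``simulate_prey_assay`` — binomial uptake counts and Poisson avoidance
  counts over a prey exposure.
* ``simulate_expression_cells`` — per-cell fluorescence intensities with
  condition-dependent means along a rostro-caudal axis.

All randomness flows from one integer seed through a named generator per
simulator, so adding one simulator never perturbs another's stream, and
identical seed + config reproduce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk

from .behavior import InteractionEvent
from .errors import ConfigurationError, GenerationError
from .imaging import RoiRecord
from .protocol import PHASE_STIM, StimulusProtocol

_STREAMS = {"imaging": 101, "behavior": 202, "prey": 303, "expression": 404}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent substream for one named simulator."""
    if stream not in _STREAMS:
        raise ConfigurationError(f"unknown stream {stream!r}")
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STREAMS[stream]]))


# ---------------------------------------------------------------------------
# imaging forward model
# ---------------------------------------------------------------------------

@dataclass
class NeuronGroundTruth:
    """Generative parameters of one synthetic tectal neuron."""

    roi_id: int
    centroid_xy: tuple[float, float]
    ap_scale_position: float  # in [1, 10] along the tectal diagonal
    preferred_log_size: float  # log10 degrees
    tuning_width: float  # Gaussian sigma, log10 degrees
    peak_dff: float
    baseline_f0: float
    noise_sd: float
    responsive_flag: bool

    def __post_init__(self) -> None:
        if self.baseline_f0 <= 0 or self.tuning_width <= 0:
            raise ConfigurationError("baseline_f0 and tuning_width must be > 0")
        if self.peak_dff < 0 or not 1.0 <= self.ap_scale_position <= 10.0:
            raise ConfigurationError("invalid ground-truth parameters")


@dataclass
class PopulationConfig:
    """Population-level generative conditions for one imaging session.

    ``tuning_shift_log10`` models the satiety/MTII shift of preferred sizes
    toward larger stimuli; ``ap_gradient_slope`` is the change of mean
    preferred log10 size per unit A-P scale (negative: posterior prefers
    smaller); ``attenuation_small`` multiplies the response amplitude of
    neurons preferring sizes <= 5° (dominant-negative receptor stand-in,
    1.0 = no attenuation).
    """

    n_neurons: int = 200
    condition: str = "starved"
    tuning_shift_log10: float = 0.0
    ap_gradient_slope: float = -0.05
    attenuation_small: float = 1.0
    seed: int = 0
    # population distribution of tuning parameters
    mean_preferred_log_size: float = math.log10(5.0)
    preferred_sd_log10: float = 0.25
    tuning_width_log10: float = 0.3
    peak_dff_mean: float = 2.0
    peak_dff_sd: float = 0.6
    baseline_f0: float = 100.0
    noise_sd: float = 2.0
    tau_rise_s: float = 0.5
    tau_decay_s: float = 1.5
    image_shape: tuple[int, int] = (128, 128)
    centroid_jitter_px: float = 3.0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ConfigurationError("n_neurons must be positive")
        if not 0.0 <= self.attenuation_small <= 1.0:
            raise ConfigurationError("attenuation_small must lie in [0, 1]")
        if self.noise_sd < 0 or self.tau_rise_s < 0 or self.tau_decay_s < 0:
            raise ConfigurationError("noise and time constants must be >= 0")


def default_ap_axis(image_shape: tuple[int, int]
                    ) -> tuple[tuple[float, float], tuple[float, float]]:
    """Anterior->posterior diagonal used by the generator's centroid layout."""
    h, w = image_shape
    margin = 8.0
    return (margin, margin), (w - 1 - margin, h - 1 - margin)


def tuning_curve(truth: NeuronGroundTruth, sizes_deg) -> np.ndarray:
    """Expected peak ΔF/F response at each angular size (closed form)."""
    log_sizes = np.log10(np.asarray(sizes_deg, dtype=float))
    return truth.peak_dff * np.exp(
        -((log_sizes - truth.preferred_log_size) ** 2)
        / (2.0 * truth.tuning_width ** 2))


def expected_wmr(truth: NeuronGroundTruth, sizes_deg) -> float:
    """Closed-form WMR of the ground-truth tuning curve at protocol sizes."""
    r = tuning_curve(truth, sizes_deg)
    w = r / r.sum()
    return float(10.0 ** np.dot(w, np.log10(np.asarray(sizes_deg, float))))


def _stim_drive(protocol: StimulusProtocol,
                amplitudes: Mapping[float, float]) -> np.ndarray:
    """Per-frame target ΔF/F: the tuning-curve amplitude during stimulus
    phases of each size, zero elsewhere."""
    target = np.zeros(protocol.n_frames)
    for phase, size, _rep, _d, start, stop in protocol.iter_blocks():
        if phase == PHASE_STIM:
            target[start:stop] = amplitudes[size]
    return target


def _kinetics(target: np.ndarray, frame_rate_hz: float,
              tau_rise_s: float, tau_decay_s: float) -> np.ndarray:
    """First-order rise/decay toward the per-frame target.

    tau = 0 means instantaneous tracking of the target.
    """
    dt = 1.0 / frame_rate_hz
    a_rise = 1.0 if tau_rise_s == 0 else 1.0 - math.exp(-dt / tau_rise_s)
    a_decay = 1.0 if tau_decay_s == 0 else 1.0 - math.exp(-dt / tau_decay_s)
    d = np.zeros_like(target)
    level = 0.0
    for t in range(target.size):
        alpha = a_rise if target[t] > level else a_decay
        level = level + (target[t] - level) * alpha
        d[t] = level
    return d


def simulate_imaging_session(protocol: StimulusProtocol,
                             pop: PopulationConfig,
                             ) -> tuple[list[RoiRecord],
                                        list[NeuronGroundTruth]]:
    """Simulate raw ROI traces for one population under one condition.

    Per neuron the raw trace is F(t) = F0 (1 + d(t)) + eps(t), where d(t)
    relaxes with first-order kinetics toward the tuning-curve amplitude
    during stimulus phases and toward zero otherwise, and eps is i.i.d.
    Gaussian noise.  Returns the records together with the ground truth.
    """
    rng = stream_rng(pop.seed, "imaging")
    axis_start, axis_end = default_ap_axis(pop.image_shape)
    axis = np.asarray(axis_end) - np.asarray(axis_start)
    perp = np.array([-axis[1], axis[0]]) / np.linalg.norm(axis)

    records: list[RoiRecord] = []
    truths: list[NeuronGroundTruth] = []
    sizes = np.asarray(protocol.sizes_deg)
    log_sizes = np.log10(sizes)
    for i in range(1, pop.n_neurons + 1):  # roi ids from 1; 0 is background
        ap = float(rng.uniform(1.0, 10.0))
        preferred = (pop.mean_preferred_log_size
                     + pop.ap_gradient_slope * (ap - 5.5)
                     + pop.tuning_shift_log10
                     + float(rng.normal(0.0, pop.preferred_sd_log10)))
        peak = max(float(rng.normal(pop.peak_dff_mean, pop.peak_dff_sd)), 0.0)
        if pop.attenuation_small < 1.0 and preferred <= math.log10(5.0):
            peak *= pop.attenuation_small
        frac = (ap - 1.0) / 9.0
        offset = float(rng.uniform(-pop.centroid_jitter_px,
                                   pop.centroid_jitter_px))
        centroid = np.asarray(axis_start) + frac * axis + offset * perp
        amplitudes = dict(zip(
            sizes.tolist(),
            peak * np.exp(-((log_sizes - preferred) ** 2)
                          / (2.0 * pop.tuning_width_log10 ** 2))))
        truth = NeuronGroundTruth(
            roi_id=i, centroid_xy=(float(centroid[0]), float(centroid[1])),
            ap_scale_position=ap, preferred_log_size=preferred,
            tuning_width=pop.tuning_width_log10, peak_dff=peak,
            baseline_f0=pop.baseline_f0, noise_sd=pop.noise_sd,
            responsive_flag=bool(max(amplitudes.values()) >= 0.5))
        target = _stim_drive(protocol, amplitudes)
        d = _kinetics(target, protocol.frame_rate_hz,
                      pop.tau_rise_s, pop.tau_decay_s)
        noise = rng.normal(0.0, pop.noise_sd, protocol.n_frames) \
            if pop.noise_sd > 0 else 0.0
        raw = pop.baseline_f0 * (1.0 + d) + noise
        records.append(RoiRecord(roi_id=i, centroid_xy=truth.centroid_xy,
                                 raw_f=raw))
        truths.append(truth)
    return records, truths


def render_stack(records: Sequence[RoiRecord],
                 image_shape: tuple[int, int],
                 roi_radius_px: int = 3,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize ROI traces into an image stack and a label mask.

    Each ROI is a disk of uniform per-frame intensity F(t)/area on a zero
    background, so summed-pixel extraction recovers F(t) exactly.  ROIs must
    not overlap at the given radius.
    """
    h, w = image_shape
    mask = np.zeros((h, w), dtype=np.uint16)
    footprints = []
    for rec in records:
        if rec.roi_id < 1:
            raise GenerationError("roi_id must be >= 1 (0 is background)")
        x, y = rec.centroid_xy
        rr, cc = disk((y, x), roi_radius_px, shape=(h, w))
        if rr.size == 0:
            raise GenerationError(f"ROI {rec.roi_id} lies outside the image")
        if np.any(mask[rr, cc] != 0):
            raise GenerationError(
                f"ROI {rec.roi_id} overlaps another ROI at radius "
                f"{roi_radius_px}")
        mask[rr, cc] = rec.roi_id
        footprints.append((rr, cc))
    n_frames = records[0].raw_f.size if records else 0
    stack = np.zeros((n_frames, h, w), dtype=float)
    for rec, (rr, cc) in zip(records, footprints):
        area = rr.size
        stack[:, rr, cc] = (rec.raw_f / area)[:, None]
    return stack, mask


# ---------------------------------------------------------------------------
# behavior forward model
# ---------------------------------------------------------------------------

# Per-size approach/avoid probabilities by condition.  The tables ARE the
# study conditions the behavioral analyses assume: starved larvae approach
# small prey-like dots and rarely avoid them; sated (fed) larvae avoid small
# dots at the expense of neutral interactions; large dots are avoided alike
# in every condition.  MTII treatment of starved larvae mimics the fed
# pattern; dominant-negative receptor expression or SHU9119 in fed larvae
# mimics the starved pattern.  Activity (approach+avoid) is matched across
# conditions so only valence-type contrasts are planted.
_STARVED_APPROACH = {1: 0.55, 2: 0.50, 5: 0.35, 10: 0.15, 20: 0.05, 30: 0.03}
_STARVED_AVOID = {1: 0.10, 2: 0.14, 5: 0.28, 10: 0.48, 20: 0.60, 30: 0.64}
_FED_APPROACH = {1: 0.25, 2: 0.22, 5: 0.18, 10: 0.15, 20: 0.05, 30: 0.03}
_FED_AVOID = {1: 0.40, 2: 0.42, 5: 0.45, 10: 0.48, 20: 0.60, 30: 0.64}

DEFAULT_CONDITION_TABLES: dict[str, dict[str, Mapping[float, float]]] = {
    "starved": {"p_approach": _STARVED_APPROACH, "p_avoid": _STARVED_AVOID},
    "fed": {"p_approach": _FED_APPROACH, "p_avoid": _FED_AVOID},
    "starved_MTII": {"p_approach": _FED_APPROACH, "p_avoid": _FED_AVOID},
    "DNmc4r_fed": {"p_approach": _STARVED_APPROACH,
                   "p_avoid": _STARVED_AVOID},
    "SHU9119_fed": {"p_approach": _STARVED_APPROACH,
                    "p_avoid": _STARVED_AVOID},
}


@dataclass
class BehaviorConfig:
    """Generative conditions of one size-discrimination session."""

    sizes_deg: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0, 20.0, 30.0)
    presentations_per_size: int = 9
    condition_tables: dict = field(
        default_factory=lambda: {k: {ik: dict(iv) for ik, iv in v.items()}
                                 for k, v in
                                 DEFAULT_CONDITION_TABLES.items()})
    slow_velocity_mean: float = 8.0
    fast_velocity_mean: float = 35.0
    velocity_sd: float = 3.0
    slow_mixture_midpoint_deg: float = 5.0
    slow_mixture_steepness: float = 4.0
    seed: int = 0

    def table_for(self, condition: str) -> dict[str, Mapping[float, float]]:
        if condition not in self.condition_tables:
            raise ConfigurationError(
                f"no probability table for condition {condition!r}")
        table = self.condition_tables[condition]
        for size in self.sizes_deg:
            pa = table["p_approach"][size]
            pv = table["p_avoid"][size]
            if not (0 <= pa <= 1 and 0 <= pv <= 1 and pa + pv <= 1):
                raise ConfigurationError(
                    f"invalid probabilities at size {size}: {pa}, {pv}")
        return table


def slow_swim_weight(size_deg: float, midpoint_deg: float = 5.0,
                     steepness: float = 4.0) -> float:
    """Probability that an avoidance swim is slow, logistic in log10 size.

    Slow-dominant below the midpoint (small prey-like objects), escape-like
    fast swims dominant above it.
    """
    z = steepness * (math.log10(size_deg) - math.log10(midpoint_deg))
    return 1.0 / (1.0 + math.exp(z))


def simulate_behavior_session(cfg: BehaviorConfig, condition: str,
                              larva_id: int | None = None,
                              rng: np.random.Generator | None = None,
                              ) -> list[InteractionEvent]:
    """Draw one larva's event list for one condition.

    For each size, ``presentations_per_size`` i.i.d. categorical draws over
    (approach, avoid, neutral); avoidance velocities come from a slow/fast
    Gaussian mixture whose slow weight falls with stimulus size.
    """
    table = cfg.table_for(condition)
    if rng is None:
        rng = stream_rng(cfg.seed, "behavior")
    events: list[InteractionEvent] = []
    event_id = 0
    for size in cfg.sizes_deg:
        pa = table["p_approach"][size]
        pv = table["p_avoid"][size]
        draws = rng.choice(3, size=cfg.presentations_per_size,
                           p=(pa, pv, 1.0 - pa - pv))
        for outcome in draws:
            label = ("approach", "avoidance", "neutral")[int(outcome)]
            velocity = distance = None
            if label == "avoidance":
                w_slow = slow_swim_weight(size, cfg.slow_mixture_midpoint_deg,
                                          cfg.slow_mixture_steepness)
                mean = cfg.slow_velocity_mean if rng.random() < w_slow \
                    else cfg.fast_velocity_mean
                velocity = max(float(rng.normal(mean, cfg.velocity_sd)), 0.0)
                distance = velocity * float(rng.uniform(0.2, 0.4))
            elif label == "approach":
                velocity = max(float(rng.normal(6.0, 2.0)), 0.0)
                distance = velocity * float(rng.uniform(0.2, 0.4))
            events.append(InteractionEvent(
                event_id=event_id, size_deg=float(size), label=label,
                velocity_mm_s=velocity, distance_mm=distance,
                larva_id=larva_id, condition=condition))
            event_id += 1
    return events


def simulate_cohort(cfg: BehaviorConfig, condition: str, n_larvae: int,
                    seed: int | None = None) -> pd.DataFrame:
    """Flat event table for a cohort of larvae under one condition."""
    rng = stream_rng(cfg.seed if seed is None else seed, "behavior")
    frames = []
    for larva in range(n_larvae):
        events = simulate_behavior_session(cfg, condition, larva_id=larva,
                                           rng=rng)
        frames.append(pd.DataFrame(
            [{"event_id": e.event_id, "larva_id": e.larva_id,
              "condition": e.condition, "size_deg": e.size_deg,
              "label": e.label, "velocity_mm_s": e.velocity_mm_s,
              "distance_mm": e.distance_mm} for e in events]))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# prey assay forward model
# ---------------------------------------------------------------------------

@dataclass
class PreyAssayTruth:
    """Observed counts of one prey-assay session."""

    n_prey: int
    n_uptakes: int
    n_avoidances: int
    exposure_units: float  # prey count x minutes observed
    condition: str

    def __post_init__(self) -> None:
        if min(self.n_prey, self.n_uptakes, self.n_avoidances) < 0 \
                or self.exposure_units < 0:
            raise ConfigurationError("counts and exposure must be >= 0")
        if self.n_uptakes > self.n_prey:
            raise ConfigurationError("uptakes cannot exceed prey count")


def simulate_prey_assay(n_prey: int, p_uptake: float, avoidance_rate: float,
                        exposure_units: float, condition: str,
                        seed: int = 0,
                        rng: np.random.Generator | None = None,
                        ) -> PreyAssayTruth:
    """Binomial uptakes and Poisson avoidances over a prey exposure."""
    if not 0 <= p_uptake <= 1 or avoidance_rate < 0 or exposure_units < 0:
        raise ConfigurationError("rates must be nonnegative (p in [0, 1])")
    if rng is None:
        rng = stream_rng(seed, "prey")
    uptakes = int(rng.binomial(n_prey, p_uptake))
    avoidances = int(rng.poisson(avoidance_rate * exposure_units))
    return PreyAssayTruth(n_prey=n_prey, n_uptakes=uptakes,
                          n_avoidances=avoidances,
                          exposure_units=exposure_units, condition=condition)


# ---------------------------------------------------------------------------
# expression forward model
# ---------------------------------------------------------------------------

def simulate_expression_cells(n_cells: int,
                              condition_means: Mapping[str, float],
                              axis_length: float,
                              seed: int = 0,
                              sd: float = 5.0,
                              gradient_per_unit: float = 0.0,
                              ) -> pd.DataFrame:
    """Per-cell mean gray values along a rostro-caudal axis.

    ``n_cells`` cells per condition, centroids uniform along the axis
    (x in [0, axis_length], small y jitter); intensities are Normal around
    the condition mean, optionally drifting linearly along the axis.
    """
    if any(m <= 0 for m in condition_means.values()):
        raise ConfigurationError("condition means must be positive")
    rng = stream_rng(seed, "expression")
    rows = []
    cell_id = 0
    for condition, mean in condition_means.items():
        xs = rng.uniform(0.0, axis_length, n_cells)
        ys = rng.uniform(-2.0, 2.0, n_cells)
        noise = rng.normal(0.0, sd, n_cells) if sd > 0 else np.zeros(n_cells)
        gray = np.maximum(
            mean + gradient_per_unit * xs + noise, 0.0)
        for x, y, g in zip(xs, ys, gray):
            rows.append({"cell_id": cell_id, "x": float(x), "y": float(y),
                         "mean_gray": float(g), "condition": condition})
            cell_id += 1
    return pd.DataFrame(rows)
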