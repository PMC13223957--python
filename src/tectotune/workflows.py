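"""End-to-end study workflows built from the library primitives.

Each function runs one complete in-silico experiment — simulate the inputs
under the configured study conditions, run the analysis pipeline, and
summarize — and returns a plain dict of the quantities a results section
would report.  They are the single implementation used by both the test
suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior import per_larva_summary
from .imaging import analyze_session, median_wmr, session_wmr_records
from .protocol import StimulusProtocol, make_protocol
from .simulate import (BehaviorConfig, PopulationConfig, default_ap_axis,
                       expected_wmr, simulate_cohort,
                       simulate_imaging_session)
from .stats import mann_whitney, per_size_tests

PLANTED_SMALL_SIZES = (1.0, 2.0, 5.0)


def _child_seed(seed: int, *key: int) -> int:
    """Deterministic 31-bit child seed for one sub-experiment."""
    return int(np.random.SeedSequence([int(seed), *key]).generate_state(1)[0]
               & 0x7FFFFFFF)


def tuning_shift_experiment(seed: int, n_neurons: int = 200,
                            shift_log10: float = 0.3,
                            protocol: StimulusProtocol | None = None) -> dict:
    """Recover a planted satiety/MTII-like tuning shift from two populations.

    Two synthetic populations share every generative parameter (and seed)
    except an additive shift of preferred log10 size; the shift is read back
    as the difference of the median WMR angles on the log10 scale and tested
    with Mann-Whitney.
    """
    protocol = protocol or make_protocol()
    base_cfg = PopulationConfig(n_neurons=n_neurons,
                                seed=_child_seed(seed, 1))
    shift_cfg = PopulationConfig(n_neurons=n_neurons, seed=base_cfg.seed,
                                 tuning_shift_log10=shift_log10,
                                 condition="starved_MTII")
    axis = default_ap_axis(base_cfg.image_shape)
    wmrs = {}
    for name, cfg in (("pre", base_cfg), ("post", shift_cfg)):
        records, _ = simulate_imaging_session(protocol, cfg)
        df = analyze_session(records, protocol, ap_axis=axis)
        wmrs[name] = df["wmr_deg"].dropna().to_numpy()
    median_pre = median_wmr(wmrs["pre"])
    median_post = median_wmr(wmrs["post"])
    recovered = float(np.log10(median_post) - np.log10(median_pre))
    return {
        "median_wmr_pre_deg": median_pre,
        "median_wmr_post_deg": median_post,
        "planted_shift_log10": shift_log10,
        "recovered_shift_log10": recovered,
        "mann_whitney_p": mann_whitney(wmrs["pre"], wmrs["post"]),
        "n_pre": int(wmrs["pre"].size),
        "n_post": int(wmrs["post"].size),
    }


def topography_experiment(seed: int, n_neurons: int = 200,
                          shift_log10: float = 0.3,
                          protocol: StimulusProtocol | None = None) -> dict:
    """A-P topography before a uniform tuning shift and ΔWMR after it.

    With a negative A-P gradient, anterior neurons prefer larger sizes than
    posterior ones; a uniform shift raises every region's tuning while
    preserving the within-session ordering.  Per region the measured
    |mean WMR_post - mean WMR_pre| is compared against the closed-form
    expectation from the generator's ground-truth tuning curves.
    """
    protocol = protocol or make_protocol()
    pre_cfg = PopulationConfig(n_neurons=n_neurons, seed=_child_seed(seed, 2))
    post_cfg = PopulationConfig(n_neurons=n_neurons, seed=pre_cfg.seed,
                                tuning_shift_log10=shift_log10)
    axis = default_ap_axis(pre_cfg.image_shape)
    sessions = {}
    for name, cfg in (("pre", pre_cfg), ("post", post_cfg)):
        records, truths = simulate_imaging_session(protocol, cfg)
        df = analyze_session(records, protocol, ap_axis=axis)
        truth_by_id = {t.roi_id: t for t in truths}
        df["expected_wmr"] = [
            expected_wmr(truth_by_id[rid], protocol.sizes_deg)
            for rid in df["roi_id"]]
        sessions[name] = df.dropna(subset=["wmr_deg"])
    out: dict[str, object] = {"regions": {}}
    for region in ("anterior", "medial", "posterior"):
        pre = sessions["pre"][sessions["pre"]["region"] == region]
        post = sessions["post"][sessions["post"]["region"] == region]
        se = float(np.sqrt(pre["wmr_deg"].var(ddof=1) / len(pre)
                           + post["wmr_deg"].var(ddof=1) / len(post)))
        out["regions"][region] = {
            "median_wmr_pre_deg": median_wmr(pre["wmr_deg"].to_numpy()),
            "median_wmr_post_deg": median_wmr(post["wmr_deg"].to_numpy()),
            "delta_wmr_deg": abs(post["wmr_deg"].mean()
                                 - pre["wmr_deg"].mean()),
            "expected_delta_wmr_deg": abs(post["expected_wmr"].mean()
                                          - pre["expected_wmr"].mean()),
            "se_delta_deg": se,
            "n_pre": len(pre), "n_post": len(post),
        }
    return out


def behavior_cohorts(seed: int, n_starved: int = 28, n_fed: int = 16,
                     cfg: BehaviorConfig | None = None
                     ) -> dict[str, pd.DataFrame]:
    """Per-larva per-size index tables for one starved and one fed cohort."""
    cfg = cfg or BehaviorConfig()
    starved = simulate_cohort(cfg, "starved", n_starved,
                              seed=_child_seed(seed, 3))
    fed = simulate_cohort(cfg, "fed", n_fed, seed=_child_seed(seed, 4))
    return {"starved": per_larva_summary(starved),
            "fed": per_larva_summary(fed)}


def _valence_by_size(per_larva: pd.DataFrame) -> pd.DataFrame:
    return per_larva.pivot(index="larva_id", columns="size_deg",
                           values="valence_index")


def condition_contrast_replicates(seed: int, n_replicates: int = 200,
                                  n_starved: int = 28, n_fed: int = 16,
                                  alpha: float = 0.05) -> dict:
    """Replicate the starved-vs-fed valence comparison many times.

    The generator plants condition effects only at the small sizes (1-5°).
    Per replicate, Welch t tests per size with BH adjustment within the
    size family; a replicate counts as pattern-consistent when the set of
    BH-significant sizes is nonempty and contained in the planted sizes.
    """
    planted = set(PLANTED_SMALL_SIZES)
    cfg = BehaviorConfig()
    n_consistent = n_false_positive = n_missed = 0
    for rep in range(n_replicates):
        cohorts = behavior_cohorts(_child_seed(seed, 5, rep),
                                   n_starved=n_starved, n_fed=n_fed, cfg=cfg)
        table = per_size_tests(_valence_by_size(cohorts["starved"]),
                               _valence_by_size(cohorts["fed"]),
                               test="t").table
        significant = set(table.index[table["adj_p"] < alpha])
        if significant and significant <= planted:
            n_consistent += 1
        if significant - planted:
            n_false_positive += 1
        if not (significant & planted):
            n_missed += 1
    return {
        "n_replicates": n_replicates,
        "fraction_pattern_consistent": n_consistent / n_replicates,
        "fraction_with_large_size_significance":
            n_false_positive / n_replicates,
        "fraction_missing_all_planted": n_missed / n_replicates,
    }
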