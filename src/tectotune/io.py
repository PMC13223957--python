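"""Readers and writers for the package's on-disk formats.

Stacks are multi-page grayscale TIFF, ROI masks 16-bit integer label TIFF,
everything tabular goes through headered CSV, and protocols/configs through
a JSON sidecar that records the seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .imaging import CumulativeWmrCurve, RoiRecord
from .protocol import StimulusProtocol, make_protocol


# -- image stacks -----------------------------------------------------------

def write_stack_tiff(path: str | Path, stack: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32),
                     photometric="minisblack")


def read_stack_tiff(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


def write_mask_tiff(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint16),
                     photometric="minisblack")


def read_mask_tiff(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path))


# -- traces -----------------------------------------------------------------

def write_traces_csv(path: str | Path, records: Sequence[RoiRecord]) -> None:
    """Long-format trace table with columns (roi_id, frame, F)."""
    frames = [pd.DataFrame({"roi_id": rec.roi_id,
                            "frame": np.arange(rec.raw_f.size),
                            "F": rec.raw_f})
              for rec in records]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_centroids_csv(path: str | Path,
                        records: Sequence[RoiRecord]) -> None:
    pd.DataFrame([{"roi_id": r.roi_id, "x": r.centroid_xy[0],
                   "y": r.centroid_xy[1]} for r in records]
                 ).to_csv(path, index=False)


def read_traces_csv(path: str | Path,
                    centroids_path: str | Path | None = None
                    ) -> list[RoiRecord]:
    """Rebuild RoiRecords from a trace CSV (+ optional centroid table)."""
    df = pd.read_csv(path)
    centroids = {}
    if centroids_path is not None:
        cdf = pd.read_csv(centroids_path)
        centroids = {int(r.roi_id): (float(r.x), float(r.y))
                     for r in cdf.itertuples()}
    records = []
    for roi_id, grp in df.groupby("roi_id"):
        grp = grp.sort_values("frame")
        records.append(RoiRecord(
            roi_id=int(roi_id),
            centroid_xy=centroids.get(int(roi_id), (float("nan"),
                                                    float("nan"))),
            raw_f=grp["F"].to_numpy(dtype=float)))
    return records


# -- protocol sidecar -------------------------------------------------------

def write_protocol_json(path: str | Path, protocol: StimulusProtocol,
                        extra: dict | None = None) -> None:
    payload = dataclasses.asdict(protocol)
    if extra:
        payload["config"] = extra
    Path(path).write_text(json.dumps(payload, indent=2))


def read_protocol_json(path: str | Path) -> StimulusProtocol:
    payload = json.loads(Path(path).read_text())
    payload.pop("config", None)
    return make_protocol(payload)


# -- results ----------------------------------------------------------------

def write_session_results_csv(path: str | Path,
                              session_df: pd.DataFrame) -> None:
    session_df.to_csv(path, index=False)


def write_curve_csv(path: str | Path, curve: CumulativeWmrCurve) -> None:
    pd.DataFrame({"wmr_angle_deg": curve.angles_deg,
                  "cumulative_pct": curve.cumulative_pct}
                 ).to_csv(path, index=False)


def write_events_csv(path: str | Path, events_df: pd.DataFrame) -> None:
    events_df.to_csv(path, index=False)


def read_events_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cells_csv(path: str | Path, cells_df: pd.DataFrame) -> None:
    cells_df.to_csv(path, index=False)


def read_cells_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
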