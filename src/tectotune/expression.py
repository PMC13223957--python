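"""Per-cell fluorescence quantification for in situ expression data.

Mean gray values of manually selected cells are min-max normalized against
the pooled extremes of all feeding states, so a value of 1 is the brightest
cell observed anywhere in the comparison.  Cell centroids are projected onto
a configured rostro-caudal axis for spatial expression profiles, and a
depth-intensity profile summarizes neuropil fluorescence as a function of
distance from the skin surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError


@dataclass
class ExpressionCell:
    """One selected cell: centroid (pixels), mean gray value, condition."""

    cell_id: int
    centroid_xy: tuple[float, float]
    mean_gray: float
    condition: str
    normalized: float | None = None

    def __post_init__(self) -> None:
        if self.mean_gray < 0:
            raise ValueError("mean_gray must be nonnegative")


def normalize_pooled_minmax(cells: pd.DataFrame) -> pd.DataFrame:
    """Min-max normalize ``mean_gray`` against the pooled extremes.

    Pools every condition to find the global minimum and maximum gray value,
    then maps each cell to (g - g_min)/(g_max - g_min); the dimmest observed
    cell maps to 0 and the brightest to 1 regardless of its condition.
    Returns a copy with a ``normalized`` column.
    """
    if len(cells) < 2:
        raise ConfigurationError("need at least 2 cells to normalize")
    g = cells["mean_gray"].to_numpy(dtype=float)
    g_min, g_max = float(g.min()), float(g.max())
    if g_max == g_min:
        raise ConfigurationError(
            "all mean gray values are equal: normalization range degenerate")
    out = cells.copy()
    out["normalized"] = (g - g_min) / (g_max - g_min)
    return out


def map_rostrocaudal(cells: pd.DataFrame,
                     axis: tuple[tuple[float, float], tuple[float, float]],
                     value: str = "normalized") -> pd.DataFrame:
    """Project cell centroids onto an oriented rostro-caudal axis.

    ``axis`` is (rostral anchor, caudal anchor) in pixel coordinates; the
    returned table carries the clipped normalized scalar projection
    (0 = rostral anchor, 1 = caudal anchor) and the chosen intensity column,
    sorted by position.
    """
    (x1, y1), (x2, y2) = axis
    vec = np.array([x2 - x1, y2 - y1], dtype=float)
    length_sq = float(vec @ vec)
    if length_sq == 0:
        raise ConfigurationError("rostro-caudal axis has zero length")
    rel = cells[["x", "y"]].to_numpy(dtype=float) - np.array([x1, y1])
    position = np.clip(rel @ vec / length_sq, 0.0, 1.0)
    out = pd.DataFrame({
        "cell_id": cells["cell_id"].to_numpy(),
        "position": position,
        value: cells[value].to_numpy(dtype=float),
    })
    if "condition" in cells:
        out["condition"] = cells["condition"].to_numpy()
    return out.sort_values("position", kind="mergesort").reset_index(drop=True)


def depth_intensity_profile(image: np.ndarray,
                            surface_line: tuple[tuple[float, float],
                                                tuple[float, float]],
                            direction: tuple[float, float],
                            pixel_size_um: float = 1.0,
                            bin_width_um: float = 1.0,
                            normalize: bool = False) -> pd.DataFrame:
    """Mean intensity as a function of perpendicular distance from the skin.

    ``surface_line`` is a two-point line marking the skin surface in pixel
    coordinates and ``direction`` a vector pointing from the surface into
    the tissue.  Pixels are binned by their perpendicular distance from the
    line (only the tissue side is kept) at ``bin_width_um``; with
    ``normalize=True`` the profile is scaled to its own maximum.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ConfigurationError("expected a single 2-D plane")
    if bin_width_um <= 0 or pixel_size_um <= 0:
        raise ConfigurationError("bin width and pixel size must be positive")
    (x1, y1), (x2, y2) = surface_line
    along = np.array([x2 - x1, y2 - y1], dtype=float)
    norm = np.linalg.norm(along)
    if norm == 0:
        raise ConfigurationError("surface line has zero length")
    h, w = image.shape
    if not (-w <= min(x1, x2) and max(x1, x2) <= 2 * w
            and -h <= min(y1, y2) and max(y1, y2) <= 2 * h):
        raise ConfigurationError("surface line lies far outside the image")
    # unit normal oriented into the tissue
    normal = np.array([-along[1], along[0]]) / norm
    if float(normal @ np.asarray(direction, dtype=float)) < 0:
        normal = -normal
    ys, xs = np.mgrid[0:h, 0:w]
    dist_px = (xs - x1) * normal[0] + (ys - y1) * normal[1]
    dist_um = dist_px * pixel_size_um
    keep = dist_um >= 0
    if not keep.any():
        raise ConfigurationError("no pixels on the tissue side of the line")
    edges = np.arange(0.0, dist_um[keep].max() + bin_width_um, bin_width_um)
    idx = np.digitize(dist_um[keep], edges) - 1
    values = image[keep]
    means, centers = [], []
    for k in range(len(edges) - 1):
        sel = idx == k
        if sel.any():
            means.append(float(values[sel].mean()))
            centers.append(float((edges[k] + edges[k + 1]) / 2))
    profile = np.asarray(means)
    if normalize and profile.max() > 0:
        profile = profile / profile.max()
    return pd.DataFrame({"distance_um": centers, "mean_intensity": profile})
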