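"""Chorionic-to-basal depth coordinate and five-layer parcellation.

The normalized depth of a placental voxel is ``d_c / (d_c + d_b)`` where
``d_c`` and ``d_b`` are Euclidean distance-transform distances (mm) to the
chorionic (fetal-side) and basal (maternal-side) surface masks.  Depth 0 is
the chorionic surface and 1 the basal surface.  Layers partition depth into
equal-width bins labelled B (chorionic) through F (basal), matching the
five-layer vessel analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from string import ascii_uppercase

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

LAYER_NAMES = ("B", "C", "D", "E", "F")


@dataclass
class DepthField:
    """Normalized depth in [0, 1] and layer labels over the placental mask."""

    depth: np.ndarray          # NaN outside the placental mask
    layer: np.ndarray          # '' outside, else one of the layer labels
    mask: np.ndarray
    layer_names: tuple = LAYER_NAMES


def compute_depth(placental_mask, chorion_mask, basal_mask,
                  voxel_size=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Normalized chorion->basal depth on the placental mask (NaN outside)."""
    placental_mask = np.asarray(placental_mask, bool)
    chorion_mask = np.asarray(chorion_mask, bool)
    basal_mask = np.asarray(basal_mask, bool)
    if not chorion_mask.any() or not basal_mask.any():
        raise ValueError("surface masks must be non-empty")
    if np.any(chorion_mask & basal_mask):
        raise ValueError("chorionic and basal masks overlap")

    d_c = distance_transform_edt(~chorion_mask, sampling=voxel_size)
    d_b = distance_transform_edt(~basal_mask, sampling=voxel_size)
    total = d_c + d_b
    if np.any(total[placental_mask] == 0):
        raise ValueError("surface masks overlap the same placental voxel")
    depth = np.full(placental_mask.shape, np.nan)
    depth[placental_mask] = (d_c[placental_mask] / total[placental_mask])
    return depth


def assign_layers(depth: np.ndarray, n_layers: int = 5) -> np.ndarray:
    """Equal-width depth bins; depth 1.0 falls in the last (basal) layer."""
    if n_layers < 2:
        raise ValueError("need at least 2 layers")
    if n_layers == 5:
        names = LAYER_NAMES
    else:
        names = tuple(ascii_uppercase[1:1 + n_layers])
    depth = np.asarray(depth, float)
    valid = np.isfinite(depth)
    if np.any((depth[valid] < 0) | (depth[valid] > 1)):
        raise ValueError("depth values must lie in [0, 1]")
    bins = np.minimum((depth[valid] * n_layers).astype(int), n_layers - 1)
    layer = np.full(depth.shape, "", dtype=object)
    layer[valid] = np.asarray(names, dtype=object)[bins]
    return layer


def depth_field(placental_mask, chorion_mask, basal_mask,
                voxel_size=(1.0, 1.0, 1.0), n_layers: int = 5) -> DepthField:
    depth = compute_depth(placental_mask, chorion_mask, basal_mask, voxel_size)
    layer = assign_layers(depth, n_layers)
    return DepthField(depth=depth, layer=layer,
                      mask=np.asarray(placental_mask, bool),
                      layer_names=tuple(np.unique(layer[layer != ""])))


def layer_summary(t2map, segresult, voxel_index, depthfld: DepthField,
                  compartment: str = "C2-PV",
                  extra_features: dict | None = None) -> pd.DataFrame:
    """Per-layer mean T2* restricted to one compartment (or "all").

    ``voxel_index`` is the feature table's back-map so segmentation rows can
    be located in the depth volume.  Layers with no voxels of the chosen
    compartment are omitted (absent, not zero).  ``extra_features`` maps
    feature name -> volume to average alongside T2*.  With
    ``compartment="all"`` the segmentation may be None (whole-placenta
    layer means).
    """
    if compartment == "all":
        in_comp = np.ones(len(voxel_index), bool)
    else:
        in_comp = segresult.hard_label == compartment
    if not in_comp.any():
        raise ValueError(f"compartment {compartment!r} has no voxels")
    idx = voxel_index[in_comp]
    layers = depthfld.layer[tuple(idx.T)]
    t2 = t2map.t2star[tuple(idx.T)]
    rows = []
    # preserve chorion->basal order
    for name in depthfld.layer_names:
        sel = layers == name
        if not sel.any():
            continue
        row = {"layer": name, "compartment": compartment,
               "n_voxels": int(sel.sum()),
               "t2star_mean": float(np.nanmean(t2[sel]))}
        for feat, vol in (extra_features or {}).items():
            row[f"{feat}_mean"] = float(np.nanmean(vol[tuple(idx[sel].T)]))
        rows.append(row)
    return pd.DataFrame(rows)
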