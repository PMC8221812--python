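"""Quantification of registered, atlas-labeled cell coordinates.

Operates on CellTable DataFrames (x_um, y_um, z_um, region, layer, brain)
against a labeled isotropic atlas volume: reassignment of white-matter
cells near the cortical border to layer 6b, per-brain region fractions,
and volume-normalized density maps (per-layer dorsal projections and
transverse slabs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthetic import AtlasVolume

WM_REASSIGN_DIST_UM = 50.0


def _cortex_mask(atlas: AtlasVolume) -> np.ndarray:
    cortex_ids = [k for k, v in atlas.meta.items() if v["is_cortex"]]
    return np.isin(atlas.labels, cortex_ids)


def reassign_white_matter_cells(cells: pd.DataFrame, atlas: AtlasVolume,
                                max_dist_um: float = WM_REASSIGN_DIST_UM
                                ) -> pd.DataFrame:
    """Relabel white-matter cells near cortex as layer 6b of that area.

    Distance to cortex is taken from a Euclidean distance transform of the
    cortical mask at atlas voxel resolution; cells strictly closer than
    ``max_dist_um`` adopt the region of the nearest cortical voxel with
    layer '6b'.  Cortical cells and deep white-matter cells are unchanged;
    the operation is idempotent.  Equidistant ties resolve to the distance
    transform's deterministic nearest-voxel choice.
    """
    cortex = _cortex_mask(atlas)
    dist, idx = ndimage.distance_transform_edt(
        ~cortex, sampling=atlas.voxel_size_um, return_indices=True)
    wm_ids = {k for k, v in atlas.meta.items() if v["is_white_matter"]}

    out = cells.copy()
    vs = atlas.voxel_size_um
    shape = atlas.labels.shape
    vox = np.clip((out[["x_um", "y_um", "z_um"]].to_numpy() / vs).astype(int),
                  0, np.array(shape) - 1)
    labels = atlas.labels[vox[:, 0], vox[:, 1], vox[:, 2]]
    in_wm = np.isin(labels, list(wm_ids)) if wm_ids else np.zeros(len(out), bool)
    near = dist[vox[:, 0], vox[:, 1], vox[:, 2]] < max_dist_um
    move = in_wm & near
    if move.any():
        nearest = idx[:, vox[move, 0], vox[move, 1], vox[move, 2]].T
        nearest_labels = atlas.labels[nearest[:, 0], nearest[:, 1],
                                      nearest[:, 2]]
        regions = [atlas.meta[int(l)]["region"] for l in nearest_labels]
        out.loc[move, "region"] = regions
        out.loc[move, "layer"] = "6b"
    return out


def region_fractions(cells: pd.DataFrame) -> pd.DataFrame:
    """Counts per region as a fraction of detected cells per brain."""
    if len(cells) == 0:
        raise ValueError("empty cell table")
    counts = cells.groupby(["brain", "region"]).size().rename("count")
    totals = cells.groupby("brain").size().rename("total")
    out = counts.reset_index().merge(totals.reset_index(), on="brain")
    out["fraction"] = out["count"] / out["total"]
    return out[["brain", "region", "count", "fraction"]]


def _layer_thickness_map(atlas: AtlasVolume, layer: str,
                         region: str | None = None) -> np.ndarray:
    """Per-column layer thickness (um) along the depth (z) axis."""
    ids = [k for k, v in atlas.meta.items()
           if v["layer"] == layer and (region is None or v["region"] == region)]
    mask = np.isin(atlas.labels, ids)
    return mask.sum(axis=2) * atlas.voxel_size_um


def density_map(cells: pd.DataFrame, atlas: AtlasVolume,
                bin_xy_um: float = 20.0, projection: str = "dorsal",
                layer: str | None = None,
                transverse_bin_um: tuple[float, float, float] = (10.0, 10.0, 200.0),
                upsample_um: float = 5.0):
    """Volume-normalized cell density maps.

    Counts are first normalized by the total number of cells of each brain
    (the table is assumed to hold one brain; normalize per brain upstream
    when averaging) and then divided by the bin volume in mm^3, so a bin
    holding 1 of 100 cells in 20 x 20 x 250 um yields (1/100)/1e-4 = 100.

    ``dorsal`` bins 20 x 20 um in the horizontal plane x the local layer
    thickness and returns a 2D array (plus a thickness mask).  ``transverse``
    bins 10 x 10 x 200 um slabs and upsamples each slab image to 5 um
    pixels with linear interpolation.
    """
    if len(cells) == 0:
        raise ValueError("empty cell table")
    total = len(cells)
    vs = atlas.voxel_size_um
    nx, ny, nz = atlas.labels.shape
    extent = np.array([nx, ny, nz]) * vs

    if projection == "dorsal":
        if layer is None:
            raise ValueError("dorsal density maps are per cortical layer")
        sub = cells[cells["layer"] == layer]
        bx = np.arange(0.0, extent[0] + bin_xy_um, bin_xy_um)
        by = np.arange(0.0, extent[1] + bin_xy_um, bin_xy_um)
        counts, _, _ = np.histogram2d(sub["x_um"], sub["y_um"], bins=[bx, by])
        thick = _layer_thickness_map(atlas, layer)
        # mean column thickness within each xy bin
        fx = int(round(bin_xy_um / vs))
        tgrid = np.zeros(counts.shape)
        for i in range(counts.shape[0]):
            for j in range(counts.shape[1]):
                block = thick[i * fx:(i + 1) * fx, j * fx:(j + 1) * fx]
                tgrid[i, j] = block.mean() if block.size else 0.0
        vol_mm3 = bin_xy_um * bin_xy_um * tgrid / 1e9
        with np.errstate(divide="ignore", invalid="ignore"):
            density = np.where(vol_mm3 > 0, (counts / total) / vol_mm3, np.nan)
        return density, vol_mm3

    if projection == "transverse":
        from skimage.transform import resize

        bxu, bzu, byu = transverse_bin_um  # x, z fine; y slabs
        bx = np.arange(0.0, extent[0] + bxu, bxu)
        bz = np.arange(0.0, extent[2] + bzu, bzu)
        slab_edges = np.arange(0.0, extent[1] + byu, byu)
        vol_mm3 = bxu * bzu * byu / 1e9
        slabs = []
        for s0, s1 in zip(slab_edges[:-1], slab_edges[1:]):
            sub = cells[(cells["y_um"] >= s0) & (cells["y_um"] < s1)]
            counts, _, _ = np.histogram2d(sub["x_um"], sub["z_um"],
                                          bins=[bx, bz])
            img = (counts / total) / vol_mm3
            factor = bxu / upsample_um
            out_shape = (int(round(img.shape[0] * factor)),
                         int(round(img.shape[1] * bzu / upsample_um)))
            slabs.append(resize(img, out_shape, order=1, mode="edge",
                                anti_aliasing=False))
        return slabs, vol_mm3

    raise ValueError("projection must be 'dorsal' or 'transverse'")
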