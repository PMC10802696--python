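"""Green-Lagrange myocardial strain from dense displacement fields.

Strain is evaluated slice-wise in 2D (radial/circumferential short-axis
strain is an in-plane quantity and slice spacing is coarse), in the
material (Lagrangian) description: tensors live at the voxels of the
reference key frame, and a field ``u`` is the forward displacement of those
material points toward the target frame.

Pipeline per phase: displacement (voxels) -> millimetres -> deformation
gradient ``F = I + grad u`` (central differences, one-sided at edges) ->
``E = 1/2 (F^T F - I)`` -> projection onto radial/circumferential unit
vectors of the region's polar coordinate system -> unweighted mean per AHA
segment.  The composed scheme (ED2K) uses the AHA map of the ED frame for
every phase; the sequential scheme (K2K) rebuilds the map at each phase's
reference key frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation

from . import aha
from .keyframes import LABEL_MYO, LABEL_RV, KeyFrameSet
from .phantom import ED2K_PAIRS, K2K_PAIRS, MaskStack
from .registration import DisplacementFieldSet


def deformation_gradient(field_vox: np.ndarray, spacing: tuple[float, float, float]) -> np.ndarray:
    """Per-voxel in-plane deformation gradient ``F = I + grad u``.

    ``field_vox`` is a (Z, Y, X, 2) displacement in voxel units (row, col);
    it is converted to mm with the (dz, dy, dx) spacing and differentiated
    per slice with central differences (one-sided at the edges).  Returns a
    (Z, Y, X, 2, 2) array.
    """
    field_vox = np.asarray(field_vox, float)
    if field_vox.ndim != 4 or field_vox.shape[-1] != 2:
        raise ValueError("expected a (slices, rows, cols, 2) field")
    _, dy, dx = spacing
    if field_vox.shape[1] < 2 or field_vox.shape[2] < 2:
        raise ValueError("in-plane extent must be at least 2 voxels")
    u_mm = np.empty_like(field_vox)
    u_mm[..., 0] = field_vox[..., 0] * dy
    u_mm[..., 1] = field_vox[..., 1] * dx
    F = np.zeros(field_vox.shape[:-1] + (2, 2))
    for z in range(field_vox.shape[0]):
        for comp in range(2):
            gy, gx = np.gradient(u_mm[z, ..., comp], dy, dx)
            F[z, ..., comp, 0] = gy
            F[z, ..., comp, 1] = gx
    F[..., 0, 0] += 1.0
    F[..., 1, 1] += 1.0
    return F


def green_lagrange(F: np.ndarray) -> np.ndarray:
    """``E = 1/2 (F^T F - I)``; symmetric, zero for rigid motion."""
    F = np.asarray(F, float)
    FtF = np.einsum("...ji,...jk->...ik", F, F)
    E = 0.5 * (FtF - np.eye(F.shape[-1]))
    return E


@dataclass
class AhaMap:
    """Voxel-to-segment assignment with its polar coordinate systems.

    ``segment_ids`` is (Z, Y, X) with 0 outside the myocardium;
    ``centres`` maps each ring to its (row, col) polar centre (the
    myocardial centroid of the region); ``alpha0`` is the anterior RV
    insertion angle anchoring the angular sectors.
    """

    segment_ids: np.ndarray
    ring_by_slice: dict[int, str]
    centres: dict[str, tuple[float, float]]
    alpha0: float

    def radial_directions(self) -> np.ndarray:
        """Per-voxel radial unit vector (row, col) from the region centre.

        Voxels at a polar centre get NaN (undefined direction) and are
        excluded from aggregation.
        """
        out = np.full(self.segment_ids.shape + (2,), np.nan)
        for z, ring in self.ring_by_slice.items():
            cy, cx = self.centres[ring]
            yy, xx = np.meshgrid(
                np.arange(out.shape[1], dtype=float),
                np.arange(out.shape[2], dtype=float),
                indexing="ij",
            )
            dyv, dxv = yy - cy, xx - cx
            r = np.hypot(dyv, dxv)
            with np.errstate(invalid="ignore", divide="ignore"):
                out[z, ..., 0] = np.where(r > 0, dyv / r, np.nan)
                out[z, ..., 1] = np.where(r > 0, dxv / r, np.nan)
        return out


def _anterior_insertion(labels: np.ndarray, centre: tuple[float, float]) -> float:
    """Anterior RV insertion angle from the RV/myocardium adjacency.

    Primary estimate: among RV voxels touching the myocardium, the boundary
    of their angular span on the side expected for the anterior insertion
    (60 degrees before the RV centroid direction).  Falls back to exactly
    ``RV-direction - 60 deg`` when no adjacency exists.
    """
    rv = labels == LABEL_RV
    if not np.any(rv):
        raise ValueError("cannot orient AHA map: no right-ventricle label")
    cy, cx = centre
    ys, xs = np.nonzero(rv.any(axis=0))  # project through slices
    alpha_rv = float(np.arctan2(ys.mean() - cy, xs.mean() - cx))
    fallback = alpha_rv - np.pi / 3
    myo = labels == LABEL_MYO
    touching = np.zeros(rv.shape[1:], dtype=bool)
    for z in range(labels.shape[0]):
        grown = binary_dilation(myo[z], iterations=1)
        touching |= rv[z] & grown
    if not np.any(touching):
        return fallback
    ys, xs = np.nonzero(touching)
    rel = np.angle(np.exp(1j * (np.arctan2(ys - cy, xs - cx) - alpha_rv)))
    insertions = (alpha_rv + rel.min(), alpha_rv + rel.max())
    dist = [abs(np.angle(np.exp(1j * (a - fallback)))) for a in insertions]
    return float(insertions[int(np.argmin(dist))])


def build_aha_map(masks: np.ndarray | MaskStack, frame: int | None = None) -> AhaMap:
    """Build the 16-segment AHA map from a biventricular label volume.

    Accepts a (Z, Y, X) label volume, or a (T, Z, Y, X) stack /
    :class:`MaskStack` together with ``frame``.  Slices are assumed ordered
    base -> apex along the slice axis; myocardium-bearing slices are split
    35/35/30 into basal/mid/apical regions (largest remainder, ties toward
    the base), each with its own polar centre.
    """
    if isinstance(masks, MaskStack):
        masks = masks.labels
    masks = np.asarray(masks)
    if masks.ndim == 4:
        if frame is None:
            raise ValueError("frame index required for a 4D mask stack")
        labels = masks[frame]
    else:
        labels = masks
    if labels.ndim != 3:
        raise ValueError("expected a (slices, rows, cols) label volume")

    myo = labels == LABEL_MYO
    myo_slices = [z for z in range(labels.shape[0]) if np.any(myo[z])]
    if not myo_slices:
        raise ValueError("no myocardium in mask volume")
    rings = aha.partition_slices(len(myo_slices))
    ring_by_slice = dict(zip(myo_slices, rings))

    centres: dict[str, tuple[float, float]] = {}
    for ring in aha.RINGS:
        zs = [z for z, r in ring_by_slice.items() if r == ring]
        if not zs:
            continue
        ys, xs = np.nonzero(myo[zs].reshape(len(zs), *myo.shape[1:]).any(axis=0))
        centres[ring] = (float(ys.mean()), float(xs.mean()))

    ys, xs = np.nonzero(myo.any(axis=0))
    lv_centre = (float(ys.mean()), float(xs.mean()))
    alpha0 = _anterior_insertion(labels, lv_centre)

    segment_ids = np.zeros(labels.shape, dtype=np.int16)
    for z, ring in ring_by_slice.items():
        cy, cx = centres[ring]
        yy, xx = np.nonzero(myo[z])
        alpha = np.arctan2(yy - cy, xx - cx)
        segment_ids[z, yy, xx] = aha.segment_for_angle(alpha, ring, alpha0)
    return AhaMap(segment_ids=segment_ids, ring_by_slice=ring_by_slice, centres=centres, alpha0=alpha0)


def project_strain(E: np.ndarray, amap: AhaMap) -> tuple[np.ndarray, np.ndarray]:
    """Radial and circumferential strain per voxel: ``r^T E r`` and ``c^T E c``.

    The circumferential direction is the 90-degree in-plane rotation of the
    radial one.  Voxels outside the AHA map (or at a polar centre) are NaN.
    """
    E = np.asarray(E, float)
    if E.shape[:-2] != amap.segment_ids.shape:
        raise ValueError("strain tensors and AHA map are on different grids")
    rhat = amap.radial_directions()
    chat = np.stack([-rhat[..., 1], rhat[..., 0]], axis=-1)
    err = np.einsum("...i,...ij,...j->...", rhat, E, rhat)
    ecc = np.einsum("...i,...ij,...j->...", chat, E, chat)
    outside = amap.segment_ids == 0
    err = np.where(outside, np.nan, err)
    ecc = np.where(outside, np.nan, ecc)
    return err, ecc


def _segment_means(err: np.ndarray, ecc: np.ndarray, amap: AhaMap) -> dict[int, tuple[float, float]]:
    out = {}
    for seg in aha.ALL_SEGMENTS:
        sel = (amap.segment_ids == seg) & np.isfinite(err) & np.isfinite(ecc)
        if np.any(sel):
            out[seg] = (float(err[sel].mean()), float(ecc[sel].mean()))
        else:
            out[seg] = (np.nan, np.nan)  # empty segment: imputed downstream
    return out


def strain_for_field(
    field_vox: np.ndarray, amap: AhaMap, spacing: tuple[float, float, float]
) -> dict[int, tuple[float, float]]:
    """Segment-mean (Err, Ecc) of one displacement field on a given AHA map."""
    E = green_lagrange(deformation_gradient(field_vox, spacing))
    err, ecc = project_strain(E, amap)
    return _segment_means(err, ecc, amap)


def segmental_strain(
    fields: DisplacementFieldSet,
    masks: np.ndarray | MaskStack,
    keyframes: KeyFrameSet,
    spacing: tuple[float, float, float],
) -> pd.DataFrame:
    """Segmental Err/Ecc table for both alignment schemes.

    ED2K phases all use the ED-frame AHA map with the composed fields (the
    fifth, full-cycle ED-ED entry uses the sequential chain composed around
    the cycle); K2K phases rebuild the AHA map at each reference key frame.
    Empty segments yield NaN, left to the feature stage's imputation.
    """
    if isinstance(masks, MaskStack):
        masks = masks.labels
    masks = np.asarray(masks)

    rows = []
    ed_map = build_aha_map(masks, keyframes["ED"])
    for ref, tgt in ED2K_PAIRS:
        f = fields.composed[tgt]
        per_seg = strain_for_field(f, ed_map, spacing)
        for seg in aha.ALL_SEGMENTS:
            err, ecc = per_seg[seg]
            rows.append(("ED2K", f"{ref}-{tgt}", seg, err, ecc))
    for ref, tgt in K2K_PAIRS:
        amap = build_aha_map(masks, keyframes[ref])
        per_seg = strain_for_field(fields.sequential[(ref, tgt)], amap, spacing)
        for seg in aha.ALL_SEGMENTS:
            err, ecc = per_seg[seg]
            rows.append(("K2K", f"{ref}-{tgt}", seg, err, ecc))
    return pd.DataFrame(rows, columns=["scheme", "phase", "aha_segment", "Err", "Ecc"])
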