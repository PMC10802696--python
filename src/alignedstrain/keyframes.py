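"""Cardiac key-frame detection from a global contraction-relaxation curve.

A short-axis cine sequence covers one full cardiac cycle, so all frame
arithmetic here is cyclic (mod T).  Five key frames are extracted:

========  =======================================================
ED        end-diastole: end of the diastolic relaxation plateau
MS        mid-systole: peak contraction rate
ES        end-systole: contraction ends, volume minimal
PF        peak flow: peak early-diastolic relaxation rate
MD        mid-diastole: onset of diastasis (quiescent filling)
========  =======================================================

The driving signal is the cyclic frame-to-frame change of left-ventricular
blood-pool volume, normalized to maximum magnitude 1.  Negative values mean
the ventricle is contracting, positive values that it is relaxing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

KEY_FRAME_NAMES = ("ED", "MS", "ES", "PF", "MD")

#: label values used throughout the package for the biventricular masks
LABEL_BACKGROUND, LABEL_RV, LABEL_MYO, LABEL_POOL = 0, 1, 2, 3


class NoCycleError(ValueError):
    """Raised when no cardiac cycle can be detected in a contraction curve."""


@dataclass(frozen=True)
class ContractionCurve:
    """Signed, normalized contraction-relaxation signal, one value per frame."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("contraction curve must be a 1D array with >= 2 frames")
        if not np.all(np.isfinite(v)):
            raise ValueError("contraction curve contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def n_frames(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class KeyFrameSet:
    """The five cardiac key frames as frame indices on a cyclic axis."""

    ed: int
    ms: int
    es: int
    pf: int
    md: int
    n_frames: int = 0

    def __post_init__(self) -> None:
        if self.n_frames:
            for name, idx in self.as_dict().items():
                if not 0 <= idx < self.n_frames:
                    raise ValueError(f"key frame {name}={idx} outside [0, {self.n_frames})")

    def as_dict(self) -> dict[str, int]:
        return {"ED": self.ed, "MS": self.ms, "ES": self.es, "PF": self.pf, "MD": self.md}

    def __getitem__(self, name: str) -> int:
        return self.as_dict()[name.upper()]

    def in_cyclic_order(self) -> bool:
        """True when walking forward from ED meets MS, ES, PF, MD in order (ties allowed)."""
        if not self.n_frames:
            raise ValueError("n_frames required to check cyclic order")
        # offsets in (0, T]: a later key frame landing on ED itself counts as
        # a full cycle (e.g. diastasis extending to the next end-diastole)
        offsets = [
            ((self[k] - self.ed - 1) % self.n_frames) + 1 for k in ("MS", "ES", "PF", "MD")
        ]
        return all(a <= b for a, b in zip(offsets, offsets[1:]))


def contraction_curve(
    masks: np.ndarray, pool_label: int = LABEL_POOL, smooth_window: int = 3
) -> ContractionCurve:
    """Derive the contraction-relaxation curve from a (T, Z, Y, X) label stack.

    The curve is ``(V[t+1 mod T] - V[t]) / max|dV|`` with V the blood-pool
    voxel count, so shrinking volume (contraction) gives negative values.
    Because a voxel count is quantized (partial-volume steps of whole
    voxels), the volume trace is first smoothed with a cyclic moving
    average of ``smooth_window`` frames; pass 1 to disable.
    """
    masks = np.asarray(masks)
    if masks.ndim != 4:
        raise ValueError("expected a (frames, slices, rows, cols) label stack")
    volumes = (masks == pool_label).reshape(masks.shape[0], -1).sum(axis=1).astype(float)
    if np.any(volumes == 0):
        raise ValueError("empty blood pool in at least one frame")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        padded = np.concatenate([volumes[-(smooth_window // 2):], volumes, volumes[: smooth_window // 2]])
        volumes = np.convolve(padded, kernel, mode="valid")[: volumes.size]
    return curve_from_volumes(volumes)


def curve_from_volumes(volumes: np.ndarray) -> ContractionCurve:
    """Contraction curve from a per-frame volume (or area) trace."""
    volumes = np.asarray(volumes, dtype=float)
    diffs = np.roll(volumes, -1) - volumes
    peak = np.max(np.abs(diffs))
    if peak > 0:
        diffs = diffs / peak
    return ContractionCurve(diffs)


def detect_keyframes(curve: ContractionCurve, md_threshold: float = 0.2) -> KeyFrameSet:
    """Extract the five key frames from a contraction-relaxation curve.

    Rules (ties broken toward the lower index):

    * MS: global minimum of the curve (peak contraction rate).
    * PF: global maximum (peak relaxation rate).
    * ES: first frame at/after MS (cyclically) where the curve becomes
      non-negative, i.e. the contraction has ended.
    * ED: last non-negative frame before the contraction onset preceding MS.
    * MD: first frame after PF where |curve| < ``md_threshold`` x peak
      magnitude (diastasis onset); the scan stops at ED, so on very short
      cycles MD degenerates to ED rather than overrunning it.

    Raises
    ------
    NoCycleError
        If the curve is identically zero or never changes sign.
    """
    v = curve.values
    T = curve.n_frames
    if not (np.any(v < 0) and np.any(v > 0)):
        raise NoCycleError("no cardiac cycle detectable: curve lacks a sign change")

    ms = int(np.argmin(v))
    pf = int(np.argmax(v))

    es = ms
    for step in range(1, T + 1):
        t = (ms + step) % T
        if v[t] >= 0:
            es = t
            break

    # contraction onset: walk backwards from MS to the first frame whose
    # predecessor is non-negative; ED is that predecessor.
    onset = ms
    for step in range(T):
        prev = (onset - 1) % T
        if v[prev] >= 0:
            break
        onset = prev
    ed = (onset - 1) % T

    peak = np.max(np.abs(v))
    md = ed
    for step in range(1, (ed - pf) % T + 1):
        t = (pf + step) % T
        if abs(v[t]) < md_threshold * peak:
            md = t
            break

    kf = KeyFrameSet(ed=ed, ms=ms, es=es, pf=pf, md=md, n_frames=T)
    if not kf.in_cyclic_order():
        raise NoCycleError(f"detected key frames violate cyclic order: {kf.as_dict()}")
    return kf


def cyclic_frame_diff(a: int, b: int, n_frames: int) -> int:
    """Distance between two frame indices on a cyclic axis of length ``n_frames``."""
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    if not (0 <= a < n_frames and 0 <= b < n_frames):
        raise ValueError("frame indices must lie in [0, n_frames)")
    d = abs(a - b)
    return int(min(d, n_frames - d))


def mean_cyclic_diff(detected: KeyFrameSet, truth: KeyFrameSet, n_frames: int) -> float:
    """Mean cyclic key-frame difference over the five key frames."""
    diffs = [
        cyclic_frame_diff(detected[k], truth[k], n_frames) for k in KEY_FRAME_NAMES
    ]
    return float(np.mean(diffs))
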