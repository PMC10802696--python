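"""Deformable registration of the five key-frame volumes.

Dense in-plane displacement fields are estimated for the composed pairs
(each key frame registered to end-diastole) and the sequential pairs (each
key frame registered to its cyclic predecessor) by minimizing a three-part
objective per field:

    lambda_sim  * (1 - SSIM(fixed, moving o phi))        slice-wise SSIM
  + lambda_dice * DiceLoss(s_fixed, s_moving o phi)      myocardium overlap
  + lambda_reg  * ||grad phi||^2                         smoothness

with a bilinear spatial-transformer warp in the pull convention:
``warped(p) = moving(p + phi(p))`` sampled at the fixed grid point ``p``.
A field that warps frame k onto its reference grid is therefore also the
forward displacement of the reference frame's material points toward k,
which is exactly what the strain module consumes.

The minimization is a coarse-to-fine variational scheme: the field itself
is the parameter vector, optimized with Adam using analytically derived
gradients of all three terms (image gradients chained through the warp).
The model/results split follows the usual fit/summary pattern:
``KeyFrameRegistration(cine, masks, keyframes).fit()`` returns a
:class:`RegistrationResult` holding both field sets, the loss
trajectories and overlap diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
from scipy.ndimage import map_coordinates, uniform_filter, zoom

from .keyframes import LABEL_MYO, KeyFrameSet
from .phantom import K2K_PAIRS, CineStack, MaskStack

COMPOSED_TARGETS = ("MS", "ES", "PF", "MD")


# ---------------------------------------------------------------------------
# warping


def warp(moving: np.ndarray, field: np.ndarray, order: int = 1) -> np.ndarray:
    """Warp a 2D slice or 3D volume through an in-plane displacement field.

    ``field[..., 0]`` is the row displacement, ``field[..., 1]`` the column
    displacement, both in voxels.  Out-of-bounds samples clamp to the border
    value.  For a zero field the output equals the input.
    """
    moving = np.asarray(moving, dtype=float)
    field = np.asarray(field, dtype=float)
    if field.shape[:-1] != moving.shape or field.shape[-1] != 2:
        raise ValueError(
            f"field shape {field.shape} incompatible with volume {moving.shape}"
        )
    if moving.ndim == 2:
        ny, nx = moving.shape
        yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        coords = [yy + field[..., 0], xx + field[..., 1]]
        return map_coordinates(moving, coords, order=order, mode="nearest")
    if moving.ndim == 3:
        return np.stack([warp(moving[z], field[z], order=order) for z in range(moving.shape[0])])
    raise ValueError("expected a 2D slice or 3D volume")


def warp_labels(labels: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Warp a label volume: linear interpolation per one-hot channel, then argmax.

    Labels whose best channel stays below 0.5 fall back to background 0.
    """
    labels = np.asarray(labels)
    present = np.unique(labels)
    probs = np.stack([warp((labels == lab).astype(float), field) for lab in present])
    best = np.argmax(probs, axis=0)
    out = present[best].astype(labels.dtype)
    out[np.take_along_axis(probs, best[None], axis=0)[0] < 0.5] = 0
    return out


def compose_fields(first: np.ndarray, second: np.ndarray) -> np.ndarray:
    """Compose displacements: ``(f2 o f1)(p) = f1(p) + f2(p + f1(p))``.

    ``first`` maps the reference grid into the intermediate frame, ``second``
    the intermediate grid into the target; the result maps reference ->
    target on the reference grid.
    """
    out = first.copy()
    for c in range(2):
        out[..., c] += warp(second[..., c], first)
    return out


# ---------------------------------------------------------------------------
# loss terms


def ssim_slice(
    f: np.ndarray,
    m: np.ndarray,
    window: int = 7,
    eps1: float | None = None,
    eps2: float | None = None,
    dynamic_range: float | None = None,
) -> float:
    """Mean local SSIM between two 2D slices (uniform N x N windows).

    The stabilizers default to ``(0.01 L)^2`` and ``(0.03 L)^2`` with ``L``
    the dynamic range of the fixed slice.  Returns a value in (-1, 1] and
    equals 1 for identical slices.
    """
    val, _ = _ssim_value_grad(
        np.asarray(f, float), np.asarray(m, float), window, eps1, eps2, dynamic_range
    )
    return float(val)


def _ssim_constants(
    f: np.ndarray,
    m: np.ndarray,
    eps1: float | None,
    eps2: float | None,
    dynamic_range: float | None,
) -> tuple[float, float]:
    if eps1 is None or eps2 is None:
        L = dynamic_range
        if L is None:
            # widest range over both slices, so the measure stays symmetric
            L = float(max(f.max() - f.min(), m.max() - m.min()))
        if L <= 0:
            L = 1.0
        eps1 = (0.01 * L) ** 2 if eps1 is None else eps1
        eps2 = (0.03 * L) ** 2 if eps2 is None else eps2
    return float(eps1), float(eps2)


def _ssim_value_grad(
    f: np.ndarray,
    m: np.ndarray,
    window: int,
    eps1: float | None,
    eps2: float | None,
    dynamic_range: float | None,
) -> tuple[float, np.ndarray]:
    """Mean SSIM of a slice pair and its gradient with respect to ``m``."""
    if f.shape != m.shape or f.ndim != 2:
        raise ValueError("slices must be 2D and of equal shape")
    if window % 2 == 0:
        raise ValueError("SSIM window must be odd")
    if window > min(f.shape):
        raise ValueError("SSIM window larger than slice extent")
    c1, c2 = _ssim_constants(f, m, eps1, eps2, dynamic_range)

    def B(a: np.ndarray) -> np.ndarray:
        return uniform_filter(a, size=window, mode="reflect")

    muf, mum = B(f), B(m)
    sff = B(f * f) - muf**2
    smm = B(m * m) - mum**2
    sfm = B(f * m) - muf * mum
    a1 = 2 * muf * mum + c1
    a2 = 2 * sfm + c2
    b1 = muf**2 + mum**2 + c1
    b2 = sff + smm + c2
    S = (a1 * a2) / (b1 * b2)

    P = S.size
    inv = 1.0 / (b1 * b2)
    t1 = B(2 * muf * a2 * inv - 2 * mum * S / b1)
    t2 = -2 * m * B(S / b2) + 2 * B(S * mum / b2)
    t3 = f * B(2 * a1 * inv) - B(2 * a1 * muf * inv)
    grad = (t1 + t2 + t3) / P
    return float(S.mean()), grad


def ssim_volume_loss(
    fixed: np.ndarray, moved: np.ndarray, window: int = 7, **kw
) -> float:
    """``1 - mean-over-slices SSIM``; 0 for identical volumes, minimized in training."""
    fixed, moved = np.asarray(fixed, float), np.asarray(moved, float)
    if fixed.shape != moved.shape:
        raise ValueError("volumes must have equal shapes")
    if fixed.ndim == 2:
        fixed, moved = fixed[None], moved[None]
    vals = [ssim_slice(fixed[z], moved[z], window=window, **kw) for z in range(fixed.shape[0])]
    return float(1.0 - np.mean(vals))


def dice_loss(s_fixed: np.ndarray, s_moved: np.ndarray, eps: float = 1.0) -> float:
    """Smoothed Dice loss ``1 - (2|A n B| + eps) / (|A| + |B| + eps)`` for binary masks."""
    a = np.asarray(s_fixed)
    b = np.asarray(s_moved)
    for arr in (a, b):
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1, True, False))):
            raise ValueError("dice_loss expects binary masks")
    if a.shape != b.shape:
        raise ValueError("masks must have equal shapes")
    a = a.astype(bool)
    b = b.astype(bool)
    inter = np.sum(a & b)
    return float(1.0 - (2.0 * inter + eps) / (a.sum() + b.sum() + eps))


def _soft_dice_value_grad(
    s_fixed: np.ndarray, w: np.ndarray, eps: float = 1.0
) -> tuple[float, np.ndarray]:
    """Soft Dice loss on a warped probability map and its gradient wrt the map."""
    p = 2.0 * np.sum(w * s_fixed) + eps
    q = np.sum(w) + np.sum(s_fixed) + eps
    grad = -(2.0 * s_fixed * q - p) / q**2
    return float(1.0 - p / q), grad


def smoothness(field: np.ndarray, reduction: str = "sum") -> float:
    """Squared-gradient regularizer of a displacement field.

    Forward differences along every spatial axis with replicated edges
    (boundary difference zero), summed over the squared entries; zero iff
    the field is constant and invariant to adding a constant vector.
    ``reduction="mean"`` divides by the number of field entries so the value
    is grid-size independent (used by the trainer).
    """
    val, _ = _smoothness_value_grad(np.asarray(field, float), reduction)
    return val


def _smoothness_value_grad(u: np.ndarray, reduction: str) -> tuple[float, np.ndarray]:
    spatial_axes = range(u.ndim - 1)  # last axis holds vector components
    total = 0.0
    grad = np.zeros_like(u)
    for ax in spatial_axes:
        d = np.diff(u, axis=ax)
        total += float(np.sum(d * d))
        sl_lo = [slice(None)] * u.ndim
        sl_hi = [slice(None)] * u.ndim
        sl_lo[ax] = slice(0, -1)
        sl_hi[ax] = slice(1, None)
        grad[tuple(sl_lo)] -= 2.0 * d
        grad[tuple(sl_hi)] += 2.0 * d
    if reduction == "mean":
        total /= u.size
        grad = grad / u.size
    elif reduction != "sum":
        raise ValueError("reduction must be 'sum' or 'mean'")
    return total, grad


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class LossWeights:
    """Weights of the composed/sequential similarity, Dice and smoothness terms."""

    lambda_k2ed: float = 1.0
    lambda_k2k: float = 1.0
    lambda_dice: float = 1.0
    #: weights the voxel-mean squared field gradient; the truth fields are
    #: smooth (near-affine), so a strong prior is appropriate
    lambda_reg: float = 2.0

    def __post_init__(self) -> None:
        vals = (self.lambda_k2ed, self.lambda_k2k, self.lambda_dice, self.lambda_reg)
        if any(v < 0 for v in vals):
            raise ValueError("loss weights must be non-negative")
        if self.lambda_k2ed == 0 and self.lambda_k2k == 0 and self.lambda_dice == 0:
            raise ValueError("at least one image-similarity weight must be positive")


@dataclass(frozen=True)
class RegistrationConfig:
    """Optimizer settings for the coarse-to-fine variational registration."""

    pyramid: tuple[int, ...] = (4, 2, 1)  # in-plane downsampling factors
    iterations: tuple[int, ...] = (100, 80, 60)
    learning_rate: float = 0.25  # Adam step in (level) voxels
    ssim_window: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.pyramid) != len(self.iterations):
            raise ValueError("pyramid and iterations must have equal length")


@dataclass
class DisplacementFieldSet:
    """Composed (phi_k2ED) and sequential (phi_k2k) dense field sets.

    ``composed[k]`` lives on the ED grid and carries ED's material points to
    key frame k (equivalently: warps frame k onto the ED grid); the "ED"
    entry is the full-cycle loop.  ``sequential[(a, b)]`` lives on frame a's
    grid and carries its points to the next key frame b.  Units are voxels.
    """

    composed: dict[str, np.ndarray]
    sequential: dict[tuple[str, str], np.ndarray]

    def __post_init__(self) -> None:
        for f in list(self.composed.values()) + list(self.sequential.values()):
            if f.ndim != 4 or f.shape[-1] != 2:
                raise ValueError("fields must have shape (slices, rows, cols, 2)")
            if not np.all(np.isfinite(f)):
                raise ValueError("displacement field contains non-finite entries")

    @classmethod
    def from_analytic(cls, spec, keyframes: KeyFrameSet) -> "DisplacementFieldSet":
        """Ground-truth fields from the phantom's closed-form motion."""
        from .phantom import analytic_displacement

        composed = {
            k: analytic_displacement(spec, keyframes["ED"], keyframes[k])
            for k in COMPOSED_TARGETS
        }
        composed["ED"] = analytic_displacement(spec, keyframes["ED"], keyframes["ED"])
        sequential = {
            (a, b): analytic_displacement(spec, keyframes[a], keyframes[b])
            for a, b in K2K_PAIRS
        }
        return cls(composed=composed, sequential=sequential)

    def cycle_drift(self) -> np.ndarray:
        """Magnitude of the sequential chain composed around the full cycle."""
        chain = None
        for pair in K2K_PAIRS:
            f = self.sequential[pair]
            chain = f.copy() if chain is None else compose_fields(chain, f)
        return np.linalg.norm(chain, axis=-1)


def total_loss(
    volumes: Mapping[str, np.ndarray],
    masks: Mapping[str, np.ndarray],
    fields: DisplacementFieldSet,
    weights: LossWeights = LossWeights(),
    ssim_window: int = 7,
) -> tuple[float, dict[str, float]]:
    """Three-part registration objective summed over all key-frame pairs.

    Per sequential field: ``lambda_k2k * SSIM-loss + lambda_reg * smoothness``;
    per composed field the same with ``lambda_k2ed``; each field additionally
    contributes ``lambda_dice * Dice-loss + lambda_reg * smoothness`` from its
    mask pair (the anatomical term carries its own regularizer, so smoothness
    enters twice per field).  Smoothness uses the grid-size-independent mean
    reduction.  Returns the total and a per-term breakdown.
    """
    breakdown: dict[str, float] = {}
    total = 0.0

    def mask_for(name: str) -> np.ndarray:
        if name not in masks:
            raise ValueError(f"missing mask for key frame {name}")
        return np.asarray(masks[name]).astype(float)

    def add_terms(tag: str, fixed: str, moving: str, f: np.ndarray, lam_sim: float) -> None:
        nonlocal total
        if fixed not in volumes or moving not in volumes:
            raise ValueError(f"missing volume for pair {fixed}<-{moving}")
        sim = ssim_volume_loss(volumes[fixed], warp(volumes[moving], f), window=ssim_window)
        smo = smoothness(f, reduction="mean")
        w_moved = warp(mask_for(moving), f)
        dice, _ = _soft_dice_value_grad(mask_for(fixed), w_moved)
        breakdown[f"{tag}:ssim"] = lam_sim * sim
        breakdown[f"{tag}:dice"] = weights.lambda_dice * dice
        breakdown[f"{tag}:reg"] = 2.0 * weights.lambda_reg * smo
        total += lam_sim * sim + weights.lambda_dice * dice + 2.0 * weights.lambda_reg * smo

    for a, b in K2K_PAIRS:
        if (a, b) not in fields.sequential:
            raise ValueError(f"missing sequential field for pair {(a, b)}")
        add_terms(f"k2k:{a}-{b}", a, b, fields.sequential[(a, b)], weights.lambda_k2k)
    for k in COMPOSED_TARGETS:
        if k not in fields.composed:
            raise ValueError(f"missing composed field for key frame {k}")
        add_terms(f"k2ed:{k}", "ED", k, fields.composed[k], weights.lambda_k2ed)
    return total, breakdown


# ---------------------------------------------------------------------------
# variational fitting


def _downsample_plane(vol: np.ndarray, factor: int) -> np.ndarray:
    """In-plane local-mean downsampling of a (Z, Y, X) volume."""
    if factor == 1:
        return vol.astype(float)
    z, y, x = vol.shape
    ty, tx = y - y % factor, x - x % factor
    v = vol[:, :ty, :tx].reshape(z, ty // factor, factor, tx // factor, factor)
    return v.mean(axis=(2, 4))


def _upsample_field(u: np.ndarray, target_shape: tuple[int, int, int]) -> np.ndarray:
    """Linear upsampling of a (Z, Y', X', 2) field, rescaling displacement units."""
    z, y, x, _ = u.shape
    tz, ty, tx = target_shape
    fy, fx = ty / y, tx / x
    out = np.zeros((tz, ty, tx, 2))
    for c in range(2):
        out[..., c] = zoom(u[..., c], (tz / z, fy, fx), order=1)
    out[..., 0] *= fy
    out[..., 1] *= fx
    return out


def _register_pair(
    fixed: np.ndarray,
    moving: np.ndarray,
    s_fixed: np.ndarray,
    s_moving: np.ndarray,
    lam_sim: float,
    weights: LossWeights,
    config: RegistrationConfig,
) -> tuple[np.ndarray, list[float]]:
    """Coarse-to-fine Adam minimization of the per-field objective."""
    history: list[float] = []
    u: np.ndarray | None = None
    lam_dice, lam_reg = weights.lambda_dice, weights.lambda_reg
    for factor, n_iter in zip(config.pyramid, config.iterations):
        f_l = _downsample_plane(fixed, factor)
        m_l = _downsample_plane(moving, factor)
        sf_l = _downsample_plane(s_fixed.astype(float), factor)
        sm_l = _downsample_plane(s_moving.astype(float), factor)
        shape = f_l.shape
        u = np.zeros(shape + (2,)) if u is None else _upsample_field(u, shape)
        L = float(f_l.max() - f_l.min()) or 1.0
        win = min(config.ssim_window, min(shape[1], shape[2]) // 2 * 2 - 1)
        win = max(win, 3)

        # image gradients of the moving image/mask, sampled through the warp
        gm = [np.stack(np.gradient(m_l[z]), axis=-1) for z in range(shape[0])]
        gs = [np.stack(np.gradient(sm_l[z]), axis=-1) for z in range(shape[0])]

        mom = np.zeros_like(u)
        vel = np.zeros_like(u)
        best_u, best_loss = u.copy(), np.inf
        lr, b1, b2, eps = config.learning_rate, 0.9, 0.999, 1e-8
        for it in range(n_iter):
            grad_u = np.zeros_like(u)
            loss = 0.0
            # similarity + anatomical terms, slice-wise
            ssim_sum = 0.0
            dS = np.zeros(shape)
            warped_mask = np.zeros(shape)
            for z in range(shape[0]):
                w_img = warp(m_l[z], u[z])
                s_val, g = _ssim_value_grad(f_l[z], w_img, win, None, None, L)
                ssim_sum += s_val
                dS[z] = g
                warped_mask[z] = warp(sm_l[z], u[z])
            loss += lam_sim * (1.0 - ssim_sum / shape[0])
            d_img = -lam_sim * dS / shape[0]  # dL/d(warped image)
            dice_val, d_mask = _soft_dice_value_grad(sf_l, warped_mask)
            loss += lam_dice * dice_val
            d_mask = lam_dice * d_mask
            for z in range(shape[0]):
                for c in range(2):
                    gm_c = warp(gm[z][..., c], u[z])
                    gs_c = warp(gs[z][..., c], u[z])
                    grad_u[z, ..., c] += d_img[z] * gm_c + d_mask[z] * gs_c
            smo, g_smo = _smoothness_value_grad(u, reduction="mean")
            loss += lam_reg * smo
            grad_u += lam_reg * g_smo

            history.append(loss)
            if loss < best_loss:
                best_loss, best_u = loss, u.copy()
            mom = b1 * mom + (1 - b1) * grad_u
            vel = b2 * vel + (1 - b2) * grad_u**2
            mhat = mom / (1 - b1 ** (it + 1))
            vhat = vel / (1 - b2 ** (it + 1))
            u = u - lr * mhat / (np.sqrt(vhat) + eps)
        u = best_u
    if u.shape[:-1] != fixed.shape:  # pyramid ended above full resolution
        u = _upsample_field(u, fixed.shape)
    if not np.all(np.isfinite(u)):
        raise FloatingPointError("registration diverged: non-finite field")
    return u, history


@dataclass
class KeyFrameRegistration:
    """Registration model over the five key-frame volumes of one cine stack."""

    cine: CineStack | np.ndarray
    masks: MaskStack | np.ndarray
    keyframes: KeyFrameSet
    weights: LossWeights = dc_field(default_factory=LossWeights)
    config: RegistrationConfig = dc_field(default_factory=RegistrationConfig)

    def __post_init__(self) -> None:
        self._values = self.cine.values if isinstance(self.cine, CineStack) else np.asarray(self.cine)
        self._labels = self.masks.labels if isinstance(self.masks, MaskStack) else np.asarray(self.masks)
        if self._values.shape != self._labels.shape:
            raise ValueError("cine and mask stacks must share a shape")
        for name, t in self.keyframes.as_dict().items():
            if not 0 <= t < self._values.shape[0]:
                raise ValueError(f"key frame {name}={t} outside the stack")

    def _vol(self, name: str) -> np.ndarray:
        return self._values[self.keyframes[name]].astype(float)

    def _myo(self, name: str) -> np.ndarray:
        return (self._labels[self.keyframes[name]] == LABEL_MYO).astype(float)

    def fit(self) -> "RegistrationResult":
        """Estimate all composed and sequential fields; deterministic."""
        histories: dict[str, list[float]] = {}
        sequential: dict[tuple[str, str], np.ndarray] = {}
        for a, b in K2K_PAIRS:
            f, hist = _register_pair(
                self._vol(a), self._vol(b), self._myo(a), self._myo(b),
                self.weights.lambda_k2k, self.weights, self.config,
            )
            sequential[(a, b)] = f
            histories[f"k2k:{a}-{b}"] = hist
        composed: dict[str, np.ndarray] = {}
        for k in COMPOSED_TARGETS:
            f, hist = _register_pair(
                self._vol("ED"), self._vol(k), self._myo("ED"), self._myo(k),
                self.weights.lambda_k2ed, self.weights, self.config,
            )
            composed[k] = f
            histories[f"k2ed:{k}"] = hist
        chain = None
        for pair in K2K_PAIRS:
            fseq = sequential[pair]
            chain = fseq.copy() if chain is None else compose_fields(chain, fseq)
        composed["ED"] = chain
        fields = DisplacementFieldSet(composed=composed, sequential=sequential)
        return RegistrationResult(model=self, fields=fields, histories=histories)


@dataclass
class RegistrationResult:
    """Fitted displacement fields with their loss trajectories and diagnostics."""

    model: KeyFrameRegistration
    fields: DisplacementFieldSet
    histories: dict[str, list[float]]

    def predict_fields(self) -> DisplacementFieldSet:
        """Both field sets from the fit; repeated calls return identical arrays."""
        return self.fields

    def dice_table(self) -> "pd.DataFrame":
        """Myocardium Dice before (identity warp) and after registration, per pair."""
        import pandas as pd

        rows = []
        for (a, b), f in self.fields.sequential.items():
            rows.append(("K2K", f"{a}-{b}", *self._pair_dice(a, b, f)))
        for k in COMPOSED_TARGETS:
            rows.append(("ED2K", f"ED-{k}", *self._pair_dice("ED", k, self.fields.composed[k])))
        return pd.DataFrame(rows, columns=["scheme", "pair", "dice_identity", "dice_warped"])

    def _pair_dice(self, fixed: str, moving: str, f: np.ndarray) -> tuple[float, float]:
        sf = self.model._myo(fixed) > 0.5
        sm = self.model._myo(moving) > 0.5
        before = 1.0 - dice_loss(sf, sm)
        moved = warp(sm.astype(float), f) >= 0.5
        after = 1.0 - dice_loss(sf, moved)
        return before, after

    def endpoint_error(self, reference: DisplacementFieldSet, on: str = "myocardium") -> dict[str, float]:
        """Median/mean voxel endpoint error of composed fields vs a reference set."""
        mask = self.model._myo("ED") > 0.5 if on == "myocardium" else np.ones(
            self.model._vol("ED").shape, bool
        )
        errs = []
        for k in COMPOSED_TARGETS:
            diff = self.fields.composed[k] - reference.composed[k]
            errs.append(np.linalg.norm(diff, axis=-1)[mask])
        errs = np.concatenate(errs)
        return {"median": float(np.median(errs)), "mean": float(np.mean(errs))}

    def summary(self) -> str:
        lines = ["Key-frame registration", "=" * 40]
        for tag, hist in self.histories.items():
            lines.append(f"{tag:>14s}: loss {hist[0]:.4f} -> {min(hist):.4f} ({len(hist)} iters)")
        table = self.dice_table()
        lines.append("-" * 40)
        for _, row in table.iterrows():
            lines.append(
                f"{row['scheme']:>5s} {row['pair']:>6s}: Dice {row['dice_identity']:.3f}"
                f" -> {row['dice_warped']:.3f}"
            )
        return "\n".join(lines)


def fit_registration(
    cine,
    masks,
    keyframes: KeyFrameSet,
    weights: LossWeights | None = None,
    config: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Convenience wrapper: build the model and fit it."""
    model = KeyFrameRegistration(
        cine=cine,
        masks=masks,
        keyframes=keyframes,
        weights=weights or LossWeights(),
        config=config or RegistrationConfig(),
    )
    return model.fit()


def predict_fields(result: RegistrationResult) -> DisplacementFieldSet:
    """Displacement fields of a fitted registration (deterministic)."""
    return result.predict_fields()
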