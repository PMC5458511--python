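"""Masked rigid alignment of class volumes and rotation-angle estimation.

Every class volume is aligned to a reference using only the fixed-subcomplex
(CP) region, so that residual differences between classes reflect motion of
the mobile subcomplex (RP). The RP rotation angle of an aligned volume is then
read off by a 1D rotation search about the long axis inside the RP mask.

Scores are masked normalized cross-correlations (NCC) in [-1, 1]; searches are
exhaustive on a coarse grid followed by local quadratic interpolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .geometry import rotate_array, rotation_about_axis
from .volume_io import BinaryMask, VoxelGrid, read_map

__all__ = [
    "RigidTransform",
    "AlignedEnsemble",
    "AlignmentError",
    "align_to_reference",
    "apply_transform",
    "estimate_rp_rotation",
    "RPRotationEstimator",
    "align_ensemble",
]

logger = logging.getLogger(__name__)


class AlignmentError(RuntimeError):
    pass


@dataclass
class RigidTransform:
    """Active rigid motion: rotate about the box center, then translate (A)."""

    rotation: Rotation = field(default_factory=Rotation.identity)
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.translation = np.asarray(self.translation, dtype=float)
        det = np.linalg.det(self.rotation.as_matrix())
        if abs(det - 1.0) > 1e-6:
            raise ValueError(f"rotation determinant {det} != +1")

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self`` applied after ``other``."""
        return RigidTransform(
            self.rotation * other.rotation,
            self.rotation.apply(other.translation) + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        inv = self.rotation.inv()
        return RigidTransform(inv, -inv.apply(self.translation))

    @property
    def matrix(self) -> np.ndarray:
        return self.rotation.as_matrix()

    def is_identity(self, rot_tol_deg: float = 1e-3, trans_tol: float = 1e-3) -> bool:
        return (
            np.rad2deg(self.rotation.magnitude()) < rot_tol_deg
            and np.linalg.norm(self.translation) < trans_tol
        )


@dataclass
class AlignedEnsemble:
    """Class volumes resampled into a common reference frame."""

    volumes: list[VoxelGrid]
    transforms: list[RigidTransform]
    counts: np.ndarray
    scores: np.ndarray
    cp_mask: BinaryMask | None = None
    rp_mask: BinaryMask | None = None
    class_ids: np.ndarray | None = None

    def __post_init__(self):
        if len(self.volumes) != len(self.transforms):
            raise ValueError("volumes and transforms must have equal length")
        self.counts = np.asarray(self.counts, dtype=int)

    def stack(self) -> np.ndarray:
        """(N, nx, ny, nz) float64 stack of the aligned densities."""
        return np.stack([v.data.astype(np.float64) for v in self.volumes])


def apply_transform(volume: VoxelGrid, t: RigidTransform, order: int = 1) -> VoxelGrid:
    """Resample ``volume`` under the active transform (trilinear by default)."""
    from scipy import ndimage

    c = (np.asarray(volume.shape, dtype=float) - 1.0) / 2.0
    m = t.rotation.inv().as_matrix()
    shift_vox = t.translation / volume.voxel_size
    offset = c - m @ (c + shift_vox)
    out = ndimage.affine_transform(
        volume.data.astype(np.float64),
        m,
        offset=offset,
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=order > 1,
    )
    return volume.with_data(out)


def _masked_ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    av = a[mask]
    bv = b[mask]
    av = av - av.mean()
    bv = bv - bv.mean()
    na, nb = np.linalg.norm(av), np.linalg.norm(bv)
    if na < 1e-12 or nb < 1e-12:
        return 0.0
    return float(av @ bv / (na * nb))


def _parabolic_peak(y_m: float, y_0: float, y_p: float) -> float:
    """Sub-step offset of the extremum of a parabola through three samples."""
    denom = y_m - 2.0 * y_0 + y_p
    if abs(denom) < 1e-12:
        return 0.0
    return float(np.clip(0.5 * (y_m - y_p) / denom, -0.5, 0.5))


def _best_shift(ref_m: np.ndarray, mov_m: np.ndarray, max_shift_vox: float) -> np.ndarray:
    """Translation (voxels) maximizing cross-correlation of masked volumes.

    FFT cross-correlation with parabolic sub-voxel refinement, restricted to
    ``|shift| <= max_shift_vox`` per axis.
    """
    f = np.fft.rfftn(ref_m) * np.conj(np.fft.rfftn(mov_m))
    cc = np.fft.irfftn(f, s=ref_m.shape, axes=(0, 1, 2))
    shape = np.asarray(ref_m.shape)
    r = int(np.floor(max_shift_vox))
    coords = [np.r_[0 : r + 1, s - r : s] if r > 0 else np.array([0]) for s in shape]
    sub = cc[np.ix_(*coords)]
    idx = np.unravel_index(np.argmax(sub), sub.shape)
    shift = np.array([coords[d][idx[d]] for d in range(3)], dtype=float)
    shift[shift > shape / 2] -= shape[shift > shape / 2]
    # parabolic refinement per axis on the full (wrapped) correlation grid
    peak = np.array([int(s) % shape[d] for d, s in enumerate(shift)])
    refined = shift.copy()
    for d in range(3):
        lo = list(peak)
        hi = list(peak)
        lo[d] = (peak[d] - 1) % shape[d]
        hi[d] = (peak[d] + 1) % shape[d]
        refined[d] += _parabolic_peak(cc[tuple(lo)], cc[tuple(peak)], cc[tuple(hi)])
    return np.clip(refined, -max_shift_vox, max_shift_vox)


def _euler_grid(angular_range: float, step: float) -> np.ndarray:
    if angular_range <= 0:
        return np.zeros((1, 3))
    one = np.arange(-angular_range, angular_range + 0.5 * step, step)
    g = np.stack(np.meshgrid(one, one, one, indexing="ij"), axis=-1).reshape(-1, 3)
    return g


def align_to_reference(
    volume: VoxelGrid,
    reference: VoxelGrid,
    region: BinaryMask,
    angular_range: float = 6.0,
    angular_step: float = 2.0,
    shift_range: float = 8.0,
    score_floor: float = 0.2,
) -> tuple[RigidTransform, VoxelGrid, float]:
    """Rigidly align ``volume`` onto ``reference`` scoring only inside ``region``.

    Exhaustive search over an intrinsic-Euler-angle grid (step ``angular_step``
    degrees out to ``angular_range``); at each rotation the best translation
    within ``shift_range`` Angstrom comes from FFT cross-correlation of the
    masked densities. The top rotation is refined by per-axis quadratic
    interpolation on the angle grid. Returns the transform that, applied to
    ``volume``, matches the reference, plus the aligned volume and the masked
    NCC score. A score below ``score_floor`` flags the result with a warning.
    """
    volume.require_same_grid(reference)
    if region.shape != volume.shape:
        raise ValueError("mask shape does not match the volumes")
    mask = region.data
    ref_m = np.where(mask, reference.data - reference.data[mask].mean(), 0.0)
    if np.abs(ref_m).max() < 1e-12 or np.abs(volume.data[mask]).max() < 1e-12:
        raise AlignmentError("mask region carries no density in one of the volumes")
    max_shift_vox = shift_range / volume.voxel_size

    def score_rotation(euler_deg: np.ndarray) -> tuple[float, np.ndarray]:
        rot = Rotation.from_euler("xyz", euler_deg, degrees=True)
        rotated = rotate_array(volume.data.astype(np.float64), rot)
        mov_m = np.where(mask, rotated - rotated[mask].mean(), 0.0)
        shift_vox = _best_shift(ref_m, mov_m, max_shift_vox)
        from scipy import ndimage

        shifted = ndimage.shift(rotated, shift_vox, order=1, mode="constant", cval=0.0)
        return _masked_ncc(reference.data, shifted, mask), shift_vox

    grid = _euler_grid(angular_range, angular_step)
    best = None
    for euler in grid:
        s, shift_vox = score_rotation(euler)
        if best is None or s > best[0]:
            best = (s, euler.copy(), shift_vox)
    score, euler, shift_vox = best
    # local quadratic refinement: coordinate descent with shrinking step
    for h in (angular_step, angular_step / 2.0):
        for d in range(3):
            lo, hi = euler.copy(), euler.copy()
            lo[d] -= h
            hi[d] += h
            s_lo, _ = score_rotation(lo)
            s_hi, _ = score_rotation(hi)
            cand = euler.copy()
            cand[d] += h * _parabolic_peak(s_lo, score, s_hi)
            s_cand, shift_cand = score_rotation(cand)
            if s_cand > score:
                score, euler, shift_vox = s_cand, cand, shift_cand
    t = RigidTransform(
        Rotation.from_euler("xyz", euler, degrees=True), shift_vox * volume.voxel_size
    )
    aligned = apply_transform(volume, t)
    score = _masked_ncc(reference.data, aligned.data, mask)
    if score < score_floor:
        logger.warning("alignment score %.3f below floor %.3f", score, score_floor)
    return t, aligned, score


class RPRotationEstimator:
    """Rotation-angle readout reusing one precomputed rotated-reference library.

    Rotates the reference about ``axis`` over the search grid once, masks each
    copy with the RP mask, and estimates the angle of any aligned volume by
    masked NCC against the library with parabolic sub-step refinement.
    """

    def __init__(
        self,
        reference: VoxelGrid,
        rp_mask: BinaryMask,
        axis=(0.0, 0.0, 1.0),
        angular_range: float = 30.0,
        angular_step: float = 0.5,
    ):
        if rp_mask.shape != reference.shape:
            raise ValueError("mask shape does not match the reference")
        self.thetas = np.arange(-angular_range, angular_range + 0.5 * angular_step, angular_step)
        self.step = angular_step
        self.mask = rp_mask.data
        self.reference = reference
        ref = reference.data.astype(np.float64)
        lib = []
        for th in self.thetas:
            rot = rotation_about_axis(axis, th)
            v = rotate_array(ref, rot)[self.mask]
            v = v - v.mean()
            n = np.linalg.norm(v)
            lib.append(v / n if n > 1e-12 else v)
        self._lib = np.stack(lib)

    def estimate(self, volume: VoxelGrid) -> float:
        volume.require_same_grid(self.reference)
        v = volume.data.astype(np.float64)[self.mask]
        v = v - v.mean()
        n = np.linalg.norm(v)
        if n < 1e-12:
            raise AlignmentError("no density inside the RP mask")
        profile = self._lib @ (v / n)
        if profile.max() - profile.min() < 1e-3:
            raise AlignmentError("flat correlation profile: rotation angle indeterminate")
        i = int(np.argmax(profile))
        theta = self.thetas[i]
        if 0 < i < len(self.thetas) - 1:
            theta += self.step * _parabolic_peak(profile[i - 1], profile[i], profile[i + 1])
        return float(theta)


def estimate_rp_rotation(
    aligned: VoxelGrid,
    reference: VoxelGrid,
    rp_mask: BinaryMask,
    axis=(0.0, 0.0, 1.0),
    angular_range: float = 30.0,
    angular_step: float = 0.5,
) -> float:
    """Angle of the mobile subcomplex of ``aligned`` relative to ``reference``.

    Maximizes the masked NCC between ``aligned`` and the reference rotated
    about ``axis`` inside ``rp_mask``; positive angles follow the package's
    right-handed convention. For batches over one reference, build an
    :class:`RPRotationEstimator` once instead.
    """
    est = RPRotationEstimator(reference, rp_mask, axis, angular_range, angular_step)
    return est.estimate(aligned)


def align_ensemble(
    manifest,
    reference: VoxelGrid,
    cp_mask: BinaryMask,
    rp_mask: BinaryMask | None = None,
    angular_range: float = 6.0,
    angular_step: float = 2.0,
    shift_range: float = 8.0,
) -> AlignedEnsemble:
    """Align every class in a manifest to the reference on the CP region.

    ``manifest`` is a TSV path or DataFrame with columns ``class_id``,
    ``map_path``, ``n_particles``. Unreadable classes are collected and
    reported together at the end; readable ones are still aligned.
    """
    if isinstance(manifest, (str, Path)):
        base = Path(manifest).parent
        df = pd.read_csv(manifest, sep="\t")
        df = df.assign(map_path=[str(base / p) for p in df["map_path"]])
    else:
        df = manifest.copy()
    volumes, transforms, scores, counts, ids = [], [], [], [], []
    failures = []
    for _, row in df.iterrows():
        try:
            vol = row["volume"] if "volume" in row else read_map(row["map_path"])
            t, aligned, score = align_to_reference(
                vol, reference, cp_mask, angular_range, angular_step, shift_range
            )
        except Exception as exc:  # collect, keep going
            failures.append((row["class_id"], str(exc)))
            continue
        volumes.append(aligned)
        transforms.append(t)
        scores.append(score)
        counts.append(int(row["n_particles"]))
        ids.append(row["class_id"])
        logger.info("class %s aligned, score %.4f", row["class_id"], score)
    if failures:
        detail = "; ".join(f"{cid}: {msg}" for cid, msg in failures)
        if not volumes:
            raise AlignmentError(f"all classes failed alignment: {detail}")
        logger.error("some classes failed alignment: %s", detail)
    ens = AlignedEnsemble(
        volumes,
        transforms,
        np.asarray(counts),
        np.asarray(scores),
        cp_mask=cp_mask,
        rp_mask=rp_mask,
        class_ids=np.asarray(ids),
    )
    ens.failures = failures
    return ens
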