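"""Iterative competitive two-state classification of particle images.

Each particle image is aligned independently against projection libraries of
two reference volumes — a rotated-state and a non-rotated-state model — and
assigned to the better-fitting reference by normalized cross-correlation. After
every iteration new volumes are reconstructed from the assigned particles by
weighted backprojection, low-pass filtered to a common resolution and
normalized, and the match is repeated (three iterations by default). The final
counts per state give the rotated-state fraction.

Matching is exhaustive over a quasi-uniform viewing-direction grid, an
in-plane rotation grid and integer pixel shifts; correlation is computed over
the full image (zero-mean, unit-norm), and exact score ties go to the
non-rotated state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation
from sklearn.base import BaseEstimator

from .geometry import (
    backproject_array,
    fibonacci_sphere_rotations,
    project_array,
    rotate_image,
)
from .volume_io import VoxelGrid, low_pass, normalize

__all__ = [
    "TwoStateClassifier",
    "TwoStateResult",
    "classify_two_state",
    "reconstruct_backprojection",
]

logger = logging.getLogger(__name__)

ROTATED, NON_ROTATED = 0, 1
STATE_NAMES = ("rotated", "non_rotated")


def _normalize_rows(mat: np.ndarray) -> np.ndarray:
    mat = mat - mat.mean(axis=1, keepdims=True)
    n = np.linalg.norm(mat, axis=1, keepdims=True)
    n[n < 1e-12] = 1.0
    return (mat / n).astype(np.float32)


class _ProjectionLibrary:
    """Normalized template bank for one reference volume."""

    def __init__(self, views: list[Rotation], inplane_deg: np.ndarray):
        self.views = views
        self.inplane_deg = inplane_deg

    def build(self, volume: np.ndarray, mask_flat: np.ndarray | None = None) -> np.ndarray:
        from scipy import ndimage

        n_views, n_ip = len(self.views), len(self.inplane_deg)
        box = volume.shape[0]
        projs = np.stack([project_array(volume, rv) for rv in self.views])
        templates = np.empty((n_views, n_ip, box * box), dtype=np.float32)
        c = (box - 1) / 2.0
        for ip, phi in enumerate(self.inplane_deg):
            if phi == 0:
                rotated = projs
            else:
                a = np.deg2rad(phi)
                r2 = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]]).T
                m = np.eye(3)
                m[1:, 1:] = r2
                offset = np.array([0.0, c, c]) - m @ np.array([0.0, c, c])
                # one batched call rotates every view's projection at once
                rotated = ndimage.affine_transform(
                    projs, m, offset=offset, order=1, mode="constant", cval=0.0, prefilter=False
                )
            templates[:, ip, :] = rotated.reshape(n_views, -1)
        out = templates.reshape(n_views * n_ip, box * box)
        if mask_flat is not None:
            out = out * mask_flat
        return _normalize_rows(out)

    def orientation(self, template_index: int) -> Rotation:
        iv, ip = divmod(template_index, len(self.inplane_deg))
        phi = self.inplane_deg[ip]
        rz = Rotation.from_euler("z", phi, degrees=True)
        return rz * self.views[iv]

    def split(self, template_index: int) -> tuple[int, float]:
        iv, ip = divmod(template_index, len(self.inplane_deg))
        return iv, float(self.inplane_deg[ip])


def _ramp_filter(image: np.ndarray) -> np.ndarray:
    """2D Fourier ramp |k| weighting: density compensation for backprojection.

    Plain smearing over-weights low frequencies by 1/|k|; pre-filtering each
    image with the ramp (as in filtered backprojection) restores a roughly
    flat transfer under uniform angular coverage.
    """
    fx = np.fft.fftfreq(image.shape[0])[:, None]
    fy = np.fft.rfftfreq(image.shape[1])[None, :]
    k = np.sqrt(fx * fx + fy * fy)
    return np.fft.irfftn(np.fft.rfftn(image) * k, s=image.shape, axes=(0, 1))


def _shift_grid(shift_range: int, shift_step: int) -> list[tuple[int, int]]:
    if shift_range <= 0:
        return [(0, 0)]
    vals = range(-shift_range, shift_range + 1, shift_step)
    return [(dx, dy) for dx in vals for dy in vals]


@dataclass
class TwoStateResult:
    """Outcome of the iterative competitive classification."""

    assignments: np.ndarray  # (iterations, n) labels, 0=rotated 1=non_rotated
    counts: np.ndarray  # (iterations, 2)
    fraction_rotated: float
    best_orientations: Rotation  # final iteration, per particle
    best_shifts: np.ndarray  # (n, 2) integer pixel shifts applied to particles
    scores: np.ndarray  # (n, 2) final NCC per state
    refs_final: tuple[VoxelGrid, VoxelGrid]
    degenerate: bool = False


class TwoStateClassifier(BaseEstimator):
    """Competitive projection-matching classifier for two conformational states.

    Parameters
    ----------
    ref_rotated, ref_nonrotated
        Reference volumes on a common grid (state 0 and state 1).
    orientation_step
        Angular spacing (deg) of the quasi-uniform viewing-direction grid.
    inplane_step
        In-plane rotation grid spacing (deg).
    shift_range, shift_step
        Integer pixel shift search, ``[-range, range]`` per axis.
    n_iterations
        Competitive alignment / reconstruction rounds.
    lowpass
        Resolution (A) both references are filtered to after each round.
    support_mask
        Zero the rebuilt references outside a fixed soft envelope derived
        from the initial references.
    ref_damping
        Fraction of the previous reference retained when a class volume is
        rebuilt (0 replaces outright). Damping keeps small classes from
        collapsing when their sparse-view reconstructions degrade.

    Attributes (after :meth:`fit`)
    ----------
    labels_, counts_per_iteration_, fraction_rotated_, result_
    """

    def __init__(
        self,
        ref_rotated: VoxelGrid = None,
        ref_nonrotated: VoxelGrid = None,
        orientation_step: float = 10.0,
        inplane_step: float = 5.0,
        shift_range: int = 3,
        shift_step: int = 3,
        n_iterations: int = 3,
        lowpass: float = 20.0,
        support_mask: bool = True,
        ref_damping: float = 0.5,
    ):
        self.ref_rotated = ref_rotated
        self.ref_nonrotated = ref_nonrotated
        self.orientation_step = orientation_step
        self.inplane_step = inplane_step
        self.shift_range = shift_range
        self.shift_step = shift_step
        self.n_iterations = n_iterations
        self.lowpass = lowpass
        self.support_mask = support_mask
        self.ref_damping = ref_damping

    # -- internals ---------------------------------------------------------

    def _prepare(self):
        if self.ref_rotated is None or self.ref_nonrotated is None:
            raise ValueError("both reference volumes are required")
        self.ref_rotated.require_same_grid(self.ref_nonrotated)
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        views = fibonacci_sphere_rotations(self.orientation_step)
        inplane = np.arange(0.0, 360.0, self.inplane_step)
        self._library = _ProjectionLibrary(views, inplane)
        self._shifts = _shift_grid(self.shift_range, self.shift_step)
        self._mask2d = self._circular_mask()

    def _circular_mask(self) -> np.ndarray:
        """Soft circular mask covering the particle in every view.

        Pixels outside the object's maximal radial extent carry noise only;
        excluding them from the correlation sharpens the score without
        view-dependent bookkeeping (the radial bound holds for all
        orientations). Radius from the initial references' support plus the
        shift search range, with a 2-pixel cosine edge.
        """
        box = self.ref_rotated.shape[0]
        c = (box - 1) / 2.0
        idx = np.indices(self.ref_rotated.shape, dtype=float)
        r3 = np.sqrt(((idx - c) ** 2).sum(axis=0))
        sup = np.zeros(self.ref_rotated.shape, dtype=bool)
        for ref in (self.ref_rotated, self.ref_nonrotated):
            sup |= ref.data > 0.05 * ref.data.max()
        radius = min(r3[sup].max() + 2.0 + self.shift_range, c)
        ii = np.indices((box, box), dtype=float)
        r2 = np.sqrt(((ii - c) ** 2).sum(axis=0))
        mask = np.clip((radius - r2) / 2.0 + 0.5, 0.0, 1.0)
        return 0.5 - 0.5 * np.cos(np.pi * mask)

    def _condition(self, ref: VoxelGrid) -> VoxelGrid:
        out = normalize(low_pass(ref, self.lowpass))
        if getattr(self, "_support", None) is not None:
            out = out.with_data(out.data * self._support)
        return out

    def _build_support(self) -> None:
        """Soft support envelope from the *initial* references.

        Reconstructed references carry background artifacts (coverage
        unevenness, ramp ringing) that otherwise destabilise the competition;
        zeroing the empty volume outside a fixed soft envelope removes them
        without ever feeding assignment results back into the mask.
        """
        if not self.support_mask:
            self._support = None
            return
        from scipy.ndimage import binary_dilation, gaussian_filter

        sup = np.zeros(self.ref_rotated.shape, dtype=bool)
        for ref in (self.ref_rotated, self.ref_nonrotated):
            d = ref.data
            sup |= d > 0.05 * d.max()
        sup = binary_dilation(sup, iterations=3)
        self._support = gaussian_filter(sup.astype(np.float64), 2.0)

    def _match(self, images: np.ndarray, refs: tuple[VoxelGrid, VoxelGrid]):
        """Best score/template/shift per particle per reference.

        Correlation is a masked NCC: both the (shifted) particle and every
        template are multiplied by the soft circular support mask, zero-mean
        normalized inside it, and compared by dot product.
        """
        n, box, _ = images.shape
        npix = box * box
        mflat = self._mask2d.ravel().astype(np.float32)
        shifted = np.empty((n, len(self._shifts), npix), dtype=np.float32)
        for si, (dx, dy) in enumerate(self._shifts):
            rolled = np.roll(images, (dx, dy), axis=(1, 2)).reshape(n, npix)
            shifted[:, si, :] = rolled.astype(np.float32) * mflat
        shifted = _normalize_rows(shifted.reshape(n * len(self._shifts), npix))
        best_scores = np.empty((n, 2), dtype=np.float64)
        best_tpl = np.empty((n, 2), dtype=np.int64)
        best_shift = np.empty((n, 2), dtype=np.int64)
        for state, ref in enumerate(refs):
            templates = self._library.build(ref.data.astype(np.float64), mflat)
            scores = shifted @ templates.T  # (n*nshift, ntpl)
            scores = scores.reshape(n, len(self._shifts), templates.shape[0])
            flat = scores.reshape(n, -1)
            idx = np.argmax(flat, axis=1)
            si, ti = np.unravel_index(idx, (len(self._shifts), templates.shape[0]))
            best_scores[:, state] = flat[np.arange(n), idx]
            best_tpl[:, state] = ti
            best_shift[:, state] = si
        return best_scores, best_tpl, best_shift

    # -- estimator surface -------------------------------------------------

    def fit(self, X, y=None):
        """Run the iterative classification on an (n, box, box) image stack."""
        self._prepare()
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError("X must be an (n, box, box) image stack")
        n = X.shape[0]
        degenerate = bool(np.allclose(self.ref_rotated.data, self.ref_nonrotated.data))
        if degenerate:
            logger.warning("identical references: classification is degenerate")
        self._build_support()
        refs = (self._condition(self.ref_rotated), self._condition(self.ref_nonrotated))
        frozen = [False, False]
        all_assign, all_counts = [], []
        for it in range(self.n_iterations):
            scores, tpls, shifts = self._match(X, refs)
            labels = np.where(scores[:, ROTATED] > scores[:, NON_ROTATED], ROTATED, NON_ROTATED)
            counts = np.array([(labels == ROTATED).sum(), (labels == NON_ROTATED).sum()])
            all_assign.append(labels)
            all_counts.append(counts)
            logger.info("iteration %d: rotated=%d non_rotated=%d", it + 1, *counts)
            if it == self.n_iterations - 1:
                break
            new_refs = list(refs)
            for state in range(2):
                members = np.where(labels == state)[0]
                if frozen[state]:
                    continue
                if len(members) < 3:
                    logger.warning(
                        "state %s emptied out (n=%d); freezing its reference",
                        STATE_NAMES[state],
                        len(members),
                    )
                    frozen[state] = True
                    continue
                recon = self._reconstruct_members(X, members, tpls[:, state], shifts[:, state])
                sd = recon.std()
                if sd < 1e-12:
                    frozen[state] = True
                    continue
                update = (recon - recon.mean()) / sd
                if self.ref_damping > 0:
                    # damped update: blend with the previous (unit-scaled)
                    # reference; stabilises small classes whose sparse-view
                    # reconstructions would otherwise degrade the competition
                    prev = refs[state].data
                    prev = (prev - prev.mean()) / prev.std()
                    update = (1.0 - self.ref_damping) * update + self.ref_damping * prev
                new_refs[state] = self._condition(
                    VoxelGrid(update, refs[state].voxel_size, refs[state].origin)
                )
            refs = tuple(new_refs)
        # final per-particle geometry from the winning reference
        final_orients, final_shifts = [], []
        for i in range(n):
            state = all_assign[-1][i]
            final_orients.append(self._library.orientation(int(tpls[i, state])))
            final_shifts.append(self._shifts[int(shifts[i, state])])
        counts = all_counts[-1]
        self.result_ = TwoStateResult(
            assignments=np.stack(all_assign),
            counts=np.stack(all_counts),
            fraction_rotated=float(counts[ROTATED] / n),
            best_orientations=Rotation.concatenate(final_orients),
            best_shifts=np.asarray(final_shifts),
            scores=scores,
            refs_final=refs,
            degenerate=degenerate,
        )
        self.labels_ = all_assign[-1]
        self.counts_per_iteration_ = self.result_.counts
        self.fraction_rotated_ = self.result_.fraction_rotated
        self.refs_final_ = refs
        return self

    def _reconstruct_members(self, X, members, tpl_idx, shift_idx) -> np.ndarray:
        box = X.shape[1]
        images, view_rots = [], []
        if not hasattr(self, "_coverage_cache"):
            self._coverage_cache = {}
        for i in members:
            iv, phi = self._library.split(int(tpl_idx[i]))
            dx, dy = self._shifts[int(shift_idx[i])]
            img = np.roll(X[i], (dx, dy), axis=(0, 1)) * self._mask2d
            if phi != 0:
                img = rotate_image(img, -phi)
            images.append(_ramp_filter(img))
            view_rots.append(iv)
        vol = np.zeros((box,) * 3)
        cov = np.zeros((box,) * 3)
        ones = np.ones((box, box))
        for img, iv in zip(images, view_rots):
            rv = self._library.views[iv]
            vol += backproject_array(img, rv, (box,) * 3)
            if iv not in self._coverage_cache:
                self._coverage_cache[iv] = backproject_array(ones, rv, (box,) * 3)
            cov += self._coverage_cache[iv]
        floor = max(1e-6, 0.1 * cov.max())
        return vol / np.maximum(cov, floor)

    def predict(self, X) -> np.ndarray:
        """Single-pass state labels against the final references."""
        if not hasattr(self, "refs_final_"):
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=np.float64)
        scores, _, _ = self._match(X, self.refs_final_)
        return np.where(scores[:, ROTATED] > scores[:, NON_ROTATED], ROTATED, NON_ROTATED)


def classify_two_state(
    particles: np.ndarray,
    ref_rotated: VoxelGrid,
    ref_nonrotated: VoxelGrid,
    orientation_grid_step: float = 10.0,
    iterations: int = 3,
    lowpass: float = 20.0,
    **kwargs,
) -> TwoStateResult:
    """Competitive two-state classification; see :class:`TwoStateClassifier`."""
    clf = TwoStateClassifier(
        ref_rotated,
        ref_nonrotated,
        orientation_step=orientation_grid_step,
        n_iterations=iterations,
        lowpass=lowpass,
        **kwargs,
    )
    clf.fit(particles)
    return clf.result_


def reconstruct_backprojection(
    images: np.ndarray,
    orientations: Rotation,
    voxel_size: float = 1.0,
    ramp_filter: bool = True,
) -> VoxelGrid:
    """Real-space weighted backprojection of images at known orientations.

    Each image is (optionally) ramp-filtered for density compensation and
    smeared along its viewing axis into the global frame; the accumulated
    density is divided by a coverage map (backprojected support) with a floor
    at 10% of its maximum to keep sparsely covered voxels from blowing up.
    Real-space backprojection blurs relative to Fourier-gridded
    reconstruction but is adequate at phantom box sizes.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim != 3 or images.shape[0] < 3:
        raise ValueError("need at least 3 images in an (n, box, box) stack")
    n, box, _ = images.shape
    axes = orientations.inv().apply(np.array([0.0, 0.0, 1.0]))
    pairwise = np.abs(axes @ axes.T)
    if np.all(pairwise > np.cos(np.deg2rad(10.0))):
        logger.warning("degenerate orientation coverage: viewing axes span < 10 degrees")
    vol = np.zeros((box,) * 3)
    cov = np.zeros((box,) * 3)
    ones = np.ones((box, box))
    for i in range(n):
        rot = orientations[i]
        img = _ramp_filter(images[i]) if ramp_filter else images[i]
        vol += backproject_array(img, rot, (box,) * 3)
        cov += backproject_array(ones, rot, (box,) * 3)
    floor = max(1e-6, 0.1 * cov.max())
    return VoxelGrid(vol / np.maximum(cov, floor), voxel_size)
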