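"""Synthetic two-body phantoms, class ensembles and particle stacks.

The generator emulates the geometry that drives the analysis: a large complex
made of a fixed barrel-shaped core (CP) and a mobile cap (RP) that rotates
about the core's long axis. Phantoms are sums of Gaussian pseudo-atoms; class
ensembles draw per-class particle counts from a multinomial whose weights are
Boltzmann factors of a chosen energy function of the rotation angle; particle
stacks are noisy 2D projections of a two-state mixture. Everything is seeded
and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .geometry import project_array, rotation_about_axis
from .volume_io import BinaryMask, VoxelGrid, write_map

__all__ = [
    "PhantomSpec",
    "EnergyFunctionSpec",
    "SyntheticEnsembleOutput",
    "TwoStateParticles",
    "default_phantom_spec",
    "default_masks",
    "render_phantom",
    "make_class_ensemble",
    "make_two_state_particles",
    "write_ensemble",
    "write_particles",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a two-rigid-body Gaussian phantom.

    ``cp_atoms`` / ``rp_atoms`` are arrays of rows ``(x, y, z, weight, sigma)``
    with coordinates in Angstrom relative to the box center. The RP body is
    rotated about ``axis`` (through the box center) before rendering.
    """

    box: int = 48
    voxel_size: float = 4.0
    cp_atoms: np.ndarray = field(default=None)
    rp_atoms: np.ndarray = field(default=None)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        for name in ("cp_atoms", "rp_atoms"):
            atoms = np.asarray(getattr(self, name), dtype=float)
            if atoms.ndim != 2 or atoms.shape[1] != 5 or atoms.shape[0] == 0:
                raise ValueError(f"{name} must be a non-empty (n, 5) array")
            object.__setattr__(self, name, atoms)
        ax = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(ax)
        if n < 1e-12:
            raise ValueError("axis must be non-zero")
        object.__setattr__(self, "axis", tuple(ax / n))
        half = self.box * self.voxel_size / 2.0
        # radial reach is rotation-invariant about the axis, so checking the
        # unrotated extent (center distance plus a 2-sigma skirt) covers all angles
        for name in ("cp_atoms", "rp_atoms"):
            atoms = getattr(self, name)
            reach = np.linalg.norm(atoms[:, :3], axis=1) + 2.0 * atoms[:, 4]
            if np.any(reach > half - 4.0 * self.voxel_size):
                raise ValueError(f"{name} do not fit in the box with a 4-voxel margin")


def default_phantom_spec(box: int = 48, voxel_size: float = 4.0, seed: int = 0) -> PhantomSpec:
    """The documented default phantom.

    CP: a stack of on-axis Gaussians (cylinder-like barrel). RP: an asymmetric
    off-axis cluster above it — asymmetry about the long axis is what makes the
    rotation angle observable.
    """
    rng = np.random.default_rng(seed)
    half = box * voxel_size / 2.0
    zmax = half - 8.0 * voxel_size
    cp_z = np.linspace(-zmax, -0.1 * half, 10)
    cp_axis = np.column_stack(
        [np.zeros(10), np.zeros(10), cp_z, np.full(10, 1.0), np.full(10, 2.0 * voxel_size)]
    )
    # off-axis surface ridges: they fix the barrel's azimuthal orientation, so
    # CP-only alignment is well posed and a global rotation cannot mimic a
    # rotation of the RP cap alone. Two ridges at different azimuths (and a
    # bump) break mirror ambiguity; their mass is comparable to the cap's.
    ridge_z = np.linspace(-0.85 * zmax, -0.15 * half, 6)
    ridge_a = np.column_stack(
        [
            np.full(6, 0.30 * half),
            np.zeros(6),
            ridge_z,
            np.full(6, 1.2),
            np.full(6, 2.0 * voxel_size),
        ]
    )
    phi_b = np.deg2rad(100.0)
    ridge_b = np.column_stack(
        [
            np.full(4, 0.27 * half * np.cos(phi_b)),
            np.full(4, 0.27 * half * np.sin(phi_b)),
            np.linspace(-0.7 * zmax, -0.25 * half, 4),
            np.full(4, 1.0),
            np.full(4, 1.8 * voxel_size),
        ]
    )
    bump = np.array([[0.0, -0.26 * half, -0.55 * zmax, 1.0, 1.8 * voxel_size]])
    cp = np.vstack([cp_axis, ridge_a, ridge_b, bump])
    n_rp = 14
    radius = rng.uniform(0.30 * half, 0.45 * half, n_rp)
    # confine azimuth to a ~80 degree sector: a compact off-axis cap whose
    # azimuthal position (the observable of interest) is unambiguous
    phi = rng.uniform(-0.7, 0.7, n_rp)
    z = rng.uniform(0.10 * half, 0.42 * half, n_rp)
    rp = np.column_stack(
        [
            radius * np.cos(phi),
            radius * np.sin(phi),
            z,
            rng.uniform(1.2, 1.8, n_rp),
            np.full(n_rp, 2.0 * voxel_size),
        ]
    )
    # on coarse lattices the (voxel-scaled) Gaussian skirts can graze the
    # safety margin; shrink positions just enough to keep the bodies inside
    allowed = half - 4.0 * voxel_size
    factor = 1.0
    for atoms in (cp, rp):
        r = np.linalg.norm(atoms[:, :3], axis=1)
        keep = r > 1e-9
        factor = min(factor, np.min((allowed - 2.0 * atoms[keep, 4]) / r[keep]))
        zreach = np.abs(atoms[:, 2]) + 2.0 * atoms[:, 4]
        if np.any(zreach > allowed):
            factor = min(factor, np.min((allowed - 2.0 * atoms[:, 4]) / np.abs(atoms[:, 2])))
    if factor < 1.0:
        cp[:, :3] *= factor * 0.999
        rp[:, :3] *= factor * 0.999
    return PhantomSpec(box=box, voxel_size=voxel_size, cp_atoms=cp, rp_atoms=rp, seed=seed)


def default_masks(spec: PhantomSpec, cp_gap: float | None = None) -> tuple[BinaryMask, BinaryMask]:
    """CP/RP masks for the default phantom: slabs below/above the body boundary.

    Slabs are invariant under rotation about the long axis, so the RP mask
    covers the moving body at every angle. The CP slab stops ``cp_gap``
    Angstrom below the boundary (default: two RP sigmas) so the mobile body's
    Gaussian skirt cannot leak into the region used for rigid alignment.
    """
    if cp_gap is None:
        cp_gap = 2.0 * float(spec.rp_atoms[:, 4].max())
    coords = _voxel_coords(spec)
    z = coords[..., 2]
    cp = BinaryMask(z < -cp_gap, spec.voxel_size)
    rp = BinaryMask(z > 0.0, spec.voxel_size)
    return cp, rp


def _voxel_coords(spec: PhantomSpec) -> np.ndarray:
    ax = (np.arange(spec.box) - (spec.box - 1) / 2.0) * spec.voxel_size
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return np.stack([x, y, z], axis=-1)


def _render_atoms(coords: np.ndarray, atoms: np.ndarray, out: np.ndarray) -> None:
    for x, y, z, w, s in atoms:
        d2 = (
            (coords[..., 0] - x) ** 2
            + (coords[..., 1] - y) ** 2
            + (coords[..., 2] - z) ** 2
        )
        out += w * np.exp(-0.5 * d2 / (s * s))


def render_phantom(spec: PhantomSpec, theta: float = 0.0) -> VoxelGrid:
    """Render the phantom with the RP body rotated by ``theta`` degrees.

    The CP body stays fixed; RP pseudo-atom positions are rotated about the
    long axis through the box center (right-handed, counterclockwise from
    +axis), then both bodies are rendered as Gaussians. Rotating coordinates
    rather than resampling keeps the total density exactly theta-independent.
    """
    rot = rotation_about_axis(spec.axis, theta)
    rp_pos = rot.apply(spec.rp_atoms[:, :3])
    half = spec.box * spec.voxel_size / 2.0
    reach = np.linalg.norm(rp_pos, axis=1) + 2.0 * spec.rp_atoms[:, 4]
    if np.any(reach > half):
        raise ValueError(f"RP body leaves the box at theta={theta}")
    coords = _voxel_coords(spec)
    out = np.zeros((spec.box,) * 3)
    _render_atoms(coords, spec.cp_atoms, out)
    rp = spec.rp_atoms.copy()
    rp[:, :3] = rp_pos
    _render_atoms(coords, rp, out)
    return VoxelGrid(out, spec.voxel_size)


# ---------------------------------------------------------------------------
# energy functions


@dataclass(frozen=True)
class EnergyFunctionSpec:
    """Free-energy profile E(theta) in units of kT over a rotation-angle domain.

    kinds
    -----
    ``flat``
        E = 0 everywhere.
    ``harmonic``
        E = 0.5 * stiffness * (theta - center)^2.
    ``double_well_barrier``
        Quartic double well with minima at ``well_centers`` and the stated
        ``barrier_height`` between them; ``well_depths`` tilts the two wells
        (0, 0) keeps them equal. The minimum over the domain is shifted to 0.
    """

    kind: str = "flat"
    domain: tuple[float, float] = (-25.0, 25.0)
    stiffness: float = 0.02
    center: float = 0.0
    well_centers: tuple[float, float] = (-15.0, 15.0)
    well_depths: tuple[float, float] = (0.0, 0.0)
    barrier_height: float = 3.0

    def __post_init__(self):
        if self.kind not in ("flat", "harmonic", "double_well_barrier"):
            raise ValueError(f"unknown energy function kind: {self.kind!r}")
        if not self.domain[1] > self.domain[0]:
            raise ValueError("domain must be an increasing interval")

    def _raw(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if self.kind == "flat":
            return np.zeros_like(theta)
        if self.kind == "harmonic":
            return 0.5 * self.stiffness * (theta - self.center) ** 2
        c1, c2 = self.well_centers
        mid, c = (c1 + c2) / 2.0, abs(c2 - c1) / 2.0
        u = theta - mid
        e = self.barrier_height * (u * u - c * c) ** 2 / c**4
        d1, d2 = self.well_depths
        if d1 != d2:
            e = e + (d2 - d1) / 2.0 * np.tanh(2.0 * u / c)
        return e

    def __call__(self, theta) -> np.ndarray:
        """Energy in kT, with min over the domain fixed at 0."""
        grid = np.linspace(self.domain[0], self.domain[1], 2001)
        return self._raw(theta) - self._raw(grid).min()


@dataclass
class SyntheticEnsembleOutput:
    """A rendered class ensemble with Boltzmann-sampled particle counts."""

    class_thetas: np.ndarray
    volumes: list[VoxelGrid]
    counts: np.ndarray
    phantom: PhantomSpec
    energy: EnergyFunctionSpec


def make_class_ensemble(
    spec: PhantomSpec,
    efun: EnergyFunctionSpec,
    n_classes: int,
    total_particles: int,
    seed: int = 0,
) -> SyntheticEnsembleOutput:
    """Render classes on an even theta grid and sample their occupancies.

    Class angles are evenly spaced over the energy function's domain; counts
    are one multinomial draw with probabilities proportional to exp(-E(theta)).
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if total_particles < n_classes:
        raise ValueError("total_particles must be >= n_classes")
    thetas = np.linspace(efun.domain[0], efun.domain[1], n_classes)
    e = efun(thetas)
    w = np.exp(-e)
    if w.sum() < 1e-300:
        raise FloatingPointError(
            "all Boltzmann weights underflow; rescale the energy function"
        )
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(total_particles, p)
    volumes = [render_phantom(spec, t) for t in thetas]
    return SyntheticEnsembleOutput(thetas, volumes, counts, spec, efun)


@dataclass
class TwoStateParticles:
    """Noisy projections of a two-state phantom mixture, with ground truth."""

    images: np.ndarray  # (n, box, box)
    labels: np.ndarray  # (n,) in {0, 1}, index into theta_states
    orientations: Rotation  # (n,) viewing rotations
    theta_states: tuple[float, float]
    fractions: tuple[float, float]
    snr: float
    phantom: PhantomSpec


def make_two_state_particles(
    spec: PhantomSpec,
    theta_states: tuple[float, float],
    fraction_state0: float,
    n_particles: int,
    snr: float = np.inf,
    seed: int = 0,
) -> TwoStateParticles:
    """Project a Bernoulli mixture of two conformations at random orientations.

    Each particle picks state 0 with probability ``fraction_state0``, is
    projected along a uniformly random orientation, and receives additive
    white Gaussian noise with variance ``var(signal)/snr`` (per image).
    ``snr=inf`` disables noise. No CTF is simulated: the classification this
    feeds operates downstream of per-particle CTF correction.
    """
    if not 0.0 <= fraction_state0 <= 1.0:
        raise ValueError("fraction_state0 must be in [0, 1]")
    if snr <= 0:
        raise ValueError("snr must be positive")
    if n_particles < 10:
        raise ValueError("need at least 10 particles")
    rng = np.random.default_rng(seed)
    vols = [render_phantom(spec, t).data.astype(np.float64) for t in theta_states]
    labels = (rng.random(n_particles) >= fraction_state0).astype(int)
    rots = Rotation.random(n_particles, rng=rng)
    images = np.empty((n_particles, spec.box, spec.box), dtype=np.float32)
    for i in range(n_particles):
        img = project_array(vols[labels[i]], rots[i])
        if np.isfinite(snr):
            sigma = np.sqrt(img.var() / snr)
            img = img + rng.normal(0.0, sigma, img.shape)
        images[i] = img
    return TwoStateParticles(
        images,
        labels,
        rots,
        tuple(theta_states),
        (fraction_state0, 1.0 - fraction_state0),
        snr,
        spec,
    )


# ---------------------------------------------------------------------------
# on-disk fixtures


def write_ensemble(ens: SyntheticEnsembleOutput, outdir) -> Path:
    """Write class maps plus a TSV manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (vol, cnt, th) in enumerate(zip(ens.volumes, ens.counts, ens.class_thetas)):
        name = f"class_{i:03d}.mrc"
        write_map(vol, outdir / name)
        rows.append({"class_id": i, "map_path": name, "n_particles": int(cnt), "theta_true": th})
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def write_particles(particles: TwoStateParticles, outdir) -> Path:
    """Write the stack as a multi-section MRC plus a TSV truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack = np.moveaxis(particles.images, 0, -1)  # sections along the slow axis
    write_map(VoxelGrid(stack, particles.phantom.voxel_size), outdir / "particles.mrc")
    quats = particles.orientations.as_quat()
    df = pd.DataFrame(
        {
            "particle_id": np.arange(len(particles.labels)),
            "label": particles.labels,
            "theta_true": [particles.theta_states[l] for l in particles.labels],
            "qx": quats[:, 0],
            "qy": quats[:, 1],
            "qz": quats[:, 2],
            "qw": quats[:, 3],
        }
    )
    truth = outdir / "truth.tsv"
    df.to_csv(truth, sep="\t", index=False)
    return truth
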