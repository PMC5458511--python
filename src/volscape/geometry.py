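"""Rotations, volume resampling and projection.

Conventions used throughout the package:

* arrays are indexed ``[x, y, z]`` in a right-handed frame;
* rotations are *active* (they move the object), applied about the geometric
  box center; a positive angle about an axis is counterclockwise when viewed
  from the tip of that axis;
* projections integrate the (rotated) volume along the array z axis, giving an
  image indexed ``[x, y]``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

__all__ = [
    "rotation_about_axis",
    "rotate_array",
    "project_array",
    "backproject_array",
    "fibonacci_sphere_rotations",
    "rotate_image",
]


def rotation_about_axis(axis, angle_deg: float) -> Rotation:
    """Right-handed rotation by ``angle_deg`` degrees about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("rotation axis must be non-zero")
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / n)


def _center(shape) -> np.ndarray:
    return (np.asarray(shape, dtype=float) - 1.0) / 2.0


def rotate_array(data: np.ndarray, rot: Rotation, order: int = 1) -> np.ndarray:
    """Actively rotate a volume about its box center.

    Output voxel ``i`` samples the input at ``R^-1 (i - c) + c`` by spline
    interpolation (trilinear by default), zero-padded outside the box.
    """
    c = _center(data.shape)
    m = rot.inv().as_matrix()
    offset = c - m @ c
    return ndimage.affine_transform(
        data, m, offset=offset, order=order, mode="constant", cval=0.0, prefilter=order > 1
    )


def project_array(data: np.ndarray, rot: Rotation | None = None, order: int = 1) -> np.ndarray:
    """Project a volume along z after an optional active rotation."""
    if rot is not None:
        data = rotate_array(data, rot, order=order)
    return data.sum(axis=2)


def backproject_array(
    image: np.ndarray, rot: Rotation, shape, order: int = 1
) -> np.ndarray:
    """Smear a 2D image back along its viewing axis into the global frame.

    Inverse of :func:`project_array` up to the null space: if
    ``image = project_array(v, R)`` the smear lives in the frame of the rotated
    volume and is carried back by ``R``.
    """
    nz = shape[2]
    rep = np.broadcast_to(image[:, :, None], (image.shape[0], image.shape[1], nz))
    c = _center(shape)
    m = rot.as_matrix()
    offset = c - m @ c
    return ndimage.affine_transform(
        np.ascontiguousarray(rep),
        m,
        offset=offset,
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=False,
        output_shape=tuple(shape),
    )


def fibonacci_sphere_rotations(step_deg: float) -> list[Rotation]:
    """Quasi-uniform viewing directions at roughly ``step_deg`` spacing.

    Directions come from a Fibonacci lattice on the sphere; each is turned into
    the minimal rotation carrying +z onto it. In-plane rotation is handled
    separately in 2D by the caller.
    """
    if step_deg <= 0:
        raise ValueError("step_deg must be positive")
    n = max(2, int(round(4 * 180.0**2 / (np.pi * step_deg**2))))
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    dirs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    zhat = np.array([0.0, 0.0, 1.0])
    rots = []
    for d in dirs:
        v = np.cross(zhat, d)
        s = np.linalg.norm(v)
        c = float(zhat @ d)
        if s < 1e-12:
            rots.append(
                Rotation.identity() if c > 0 else Rotation.from_rotvec([np.pi, 0.0, 0.0])
            )
            continue
        angle = np.arctan2(s, c)
        rots.append(Rotation.from_rotvec(angle * v / s))
    return rots


def rotate_image(image: np.ndarray, angle_deg: float, order: int = 1) -> np.ndarray:
    """Actively rotate an ``[x, y]`` image counterclockwise about its center.

    Matches the 3D convention: rotating the volume by ``Rz(angle)`` before
    projection equals rotating its projection with this function.
    """
    c = (np.asarray(image.shape, dtype=float) - 1.0) / 2.0
    a = np.deg2rad(angle_deg)
    m = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]]).T  # inverse rotation
    offset = c - m @ c
    return ndimage.affine_transform(
        image, m, offset=offset, order=order, mode="constant", cval=0.0, prefilter=order > 1
    )
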