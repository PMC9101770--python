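"""Unit-quaternion algebra for rotation time series.

Quaternions are stored as arrays whose last axis holds the four components
in ``(w, x, y, z)`` order — scalar part first, then the vector part.  This
ordering is documented everywhere because sensor exports disagree on it
(some vendors emit ``(x, y, z, w)``).

A quaternion ``q = w + x i + y j + z k`` represents a 3-D rotation when it
has unit norm.  The geodesic distance between two unit quaternions
``2 arccos Re(a^{-1} b)`` is the angle, in radians, of the rotation taking
one orientation to the other on the unit 3-sphere; its range is [0, 2π]
because antipodal quaternions (which encode the same rotation of physical
space) are kept distinct.  Callers who want the rotation-group distance on
SO(3) instead can fold the double cover with ``fold_double_cover=True``.

All functions broadcast over leading axes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "IDENTITY",
    "as_quat_array",
    "conjugate",
    "geodesic_distance",
    "hamilton_product",
    "inverse",
    "norm",
    "validate_unit",
]

#: The multiplicative identity (1, 0, 0, 0).
IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])

#: Tolerance under which a quaternion is accepted as unit-norm.
UNIT_TOL = 1e-6


def as_quat_array(q) -> np.ndarray:
    """Coerce input to a float array with a trailing axis of length 4."""
    arr = np.asarray(q, dtype=float)
    if arr.shape[-1:] != (4,):
        raise ValueError(f"quaternion array must have last axis 4, got shape {arr.shape}")
    return arr


def norm(q) -> np.ndarray:
    """Euclidean 4-norm sqrt(w² + x² + y² + z²)."""
    q = as_quat_array(q)
    return np.sqrt(np.sum(q * q, axis=-1))


def hamilton_product(a, b) -> np.ndarray:
    """Hamilton product ``ab`` under i² = j² = k² = ijk = −1.

    Non-commutative; the product of two unit quaternions is unit-norm.
    """
    a = as_quat_array(a)
    b = as_quat_array(b)
    aw, ax, ay, az = a[..., 0], a[..., 1], a[..., 2], a[..., 3]
    bw, bx, by, bz = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def conjugate(q) -> np.ndarray:
    """Conjugate (w, −x, −y, −z); equals the inverse for unit quaternions."""
    q = as_quat_array(q)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def inverse(q) -> np.ndarray:
    """Multiplicative inverse q* / ‖q‖².

    Raises
    ------
    ValueError
        If any quaternion has zero norm.
    """
    q = as_quat_array(q)
    n2 = np.sum(q * q, axis=-1)
    if np.any(n2 == 0.0):
        raise ValueError("the zero quaternion has no inverse")
    return conjugate(q) / n2[..., np.newaxis]


def validate_unit(q, tol: float = UNIT_TOL, name: str = "quaternion") -> np.ndarray:
    """Check unit norm within `tol`; return the array unchanged."""
    q = as_quat_array(q)
    dev = np.abs(norm(q) - 1.0)
    if np.any(dev > tol):
        raise ValueError(
            f"{name} is not unit-norm: max |‖q‖−1| = {float(np.max(dev)):.3e} > {tol:g}"
        )
    return q


def geodesic_distance(a, b, *, fold_double_cover: bool = False) -> np.ndarray:
    """Geodesic distance 2·arccos Re(a⁻¹b) between unit quaternions, in radians.

    The result lies in [0, 2π], is symmetric in (a, b) and is exactly 0 for
    identical inputs.  With ``fold_double_cover=True`` the distance is mapped
    to min(d, 2π − d) ∈ [0, π], identifying q with −q (distance on SO(3)).

    Raises
    ------
    ValueError
        If either input deviates from unit norm by more than 1e-6.
    """
    a = validate_unit(a, name="first operand")
    b = validate_unit(b, name="second operand")
    # for unit quaternions the inverse is the conjugate; the angle is
    # evaluated as 2·atan2(‖vec‖, Re), which is algebraically identical to
    # 2·arccos(Re) on the unit sphere but numerically stable near 0 (it is
    # exactly 0 for identical inputs, where arccos would amplify rounding)
    prod = hamilton_product(conjugate(a), b)
    re = prod[..., 0]
    vec_norm = np.sqrt(np.sum(prod[..., 1:] ** 2, axis=-1))
    d = 2.0 * np.arctan2(vec_norm, re)
    # bit-identical inputs are at distance 0 by definition; rounding in the
    # product would otherwise leave ~1e-17 residues
    d = np.where(np.all(a == b, axis=-1), 0.0, d)
    if fold_double_cover:
        d = np.minimum(d, 2.0 * np.pi - d)
    return d
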