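"""Low-level vectorized geometry: dihedrals, internal-coordinate atom
placement, and batched rigid-body (Kabsch) superposition.

All routines operate on arrays of shape (..., 3) and broadcast over
leading axes, so a whole trajectory is handled in one call.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dihedral", "place_atom", "kabsch_rotation", "fit_frames", "pairwise_rmsd"]


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Torsion angle p0-p1-p2-p3 in degrees, wrapped to (-180, 180].

    Sign convention: looking from p1 toward p2, a clockwise rotation of
    the far bond relative to the near bond is positive (IUPAC).
    """
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=-1, keepdims=True))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    ang = np.degrees(np.arctan2(-y, x))
    # arctan2 returns [-180, 180]; fold -180 onto +180 so the interval is half-open
    return np.where(ang <= -180.0, ang + 360.0, ang)


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle_deg: float,
    torsion_deg: np.ndarray | float,
) -> np.ndarray:
    """Place atom D so that |CD| = bond, angle(B,C,D) = angle_deg and
    torsion(A,B,C,D) = torsion_deg (natural extension of reference frame).

    ``torsion_deg`` may be an array broadcasting against the leading axes
    of ``a``/``b``/``c``.
    """
    theta = np.radians(angle_deg)
    phi = np.radians(np.asarray(torsion_deg))

    bc = c - b
    bc /= np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)

    d_local = np.stack(
        [
            -bond * np.cos(theta) * np.ones_like(phi),
            bond * np.sin(theta) * np.cos(phi),
            bond * np.sin(theta) * np.sin(phi),
        ],
        axis=-1,
    )
    return c + (
        d_local[..., 0:1] * bc + d_local[..., 1:2] * m + d_local[..., 2:3] * n
    )


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal rotation matrices mapping centered ``mobile`` onto centered
    ``reference``; both (..., n_atoms, 3). Proper rotations only.

    The returned R acts on row vectors: ``mobile @ R ~= reference``.
    """
    h = np.einsum("...ai,...aj->...ij", mobile, reference)
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("...ij,...jk->...ik", u, vt))
    # flip the smallest singular axis when the best orthogonal map is a reflection
    d = np.ones(u.shape[:-1])
    d[..., -1] = np.sign(det)
    return np.einsum("...ij,...j,...jk->...ik", u, d, vt)


def fit_frames(frames: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares rigid-body fit of every frame onto ``reference``.

    frames: (n_frames, n_atoms, 3); reference: (n_atoms, 3).
    Returns fitted coordinates in the reference's frame of reference.
    """
    ref_c = reference - reference.mean(axis=0)
    mob_mean = frames.mean(axis=1, keepdims=True)
    mob_c = frames - mob_mean
    rot = kabsch_rotation(mob_c, ref_c[None])
    return np.einsum("fai,fij->faj", mob_c, rot) + reference.mean(axis=0)


def pairwise_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between two conformations (n_atoms, 3) after rigid-body fit."""
    fitted = fit_frames(a[None], b)[0]
    return float(np.sqrt(np.mean(np.sum((fitted - b) ** 2, axis=-1))))
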