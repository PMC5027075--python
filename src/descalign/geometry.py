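"""Rigid-body superposition and the guarded RMSD measure.

The whole comparison model is built on the root-mean-square deviation
between two equally sized, positionally corresponding point sets after
an optimal rigid superposition (Kabsch algorithm).  Two structures with
different atom counts cannot be compared by RMSD at all; in that case a
large sentinel value ``M`` is returned instead, which downstream code
treats as "incomparable".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Sentinel cost for incomparable or over-threshold pairs.  It only has to
#: exceed every achievable cost limit L = f*K (a few tens of angstroms);
#: a fixed round constant keeps scaled integer matrices well-conditioned.
M_SENTINEL: float = 1.0e6


class DegenerateInputError(ValueError):
    """Raised when a point set is too small for a meaningful superposition."""


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid superposition of one point set onto another.

    ``rotation`` and ``translation`` map the second (mobile) set onto the
    first (fixed) set: ``x_fixed ~ rotation @ x_mobile + translation``.
    """

    rotation: np.ndarray  # (3, 3), proper rotation, det +1
    translation: np.ndarray  # (3,)
    rmsd: float  # angstrom, >= 0

    def transform(self, points: np.ndarray) -> np.ndarray:
        """Apply the rigid motion to an (n, 3) coordinate array."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation


def _as_points(p) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"expected an (n, 3) coordinate array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("coordinates must be finite")
    return arr


def superpose(fixed, mobile) -> SuperpositionResult:
    """Least-RMSD proper rigid superposition of ``mobile`` onto ``fixed``.

    Uses the Kabsch singular-value-decomposition construction with the
    usual reflection correction, so the returned rotation always has
    determinant +1.  Correspondence between the two sets is positional.

    Raises
    ------
    ValueError
        If the two sets differ in size (callers that may face unequal
        sizes must use :func:`rmsd_guarded`).
    DegenerateInputError
        If fewer than 3 points are given.
    """
    p = _as_points(fixed)
    q = _as_points(mobile)
    if p.shape[0] != q.shape[0]:
        raise ValueError(f"point sets differ in size: {p.shape[0]} vs {q.shape[0]}")
    if p.shape[0] < 3:
        raise DegenerateInputError("at least 3 points are required for superposition")
    return _kabsch(p, q)


def _kabsch(p: np.ndarray, q: np.ndarray) -> SuperpositionResult:
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    p0 = p - pc
    q0 = q - qc
    h = q0.T @ p0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    moved = q0 @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - p0) ** 2, axis=1))))
    trans = pc - rot @ qc
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def rmsd(fixed, mobile) -> float:
    """Minimal RMSD between equally sized point sets (full precision)."""
    p = _as_points(fixed)
    q = _as_points(mobile)
    if p.shape[0] != q.shape[0]:
        raise ValueError(f"point sets differ in size: {p.shape[0]} vs {q.shape[0]}")
    return _kabsch(p, q).rmsd


def rmsd_guarded(p, q, big: float = M_SENTINEL) -> float:
    """RMSD usable as an alignment cost.

    Returns ``big`` when the two point sets have different sizes (RMSD is
    undefined between structures with different atom counts); otherwise
    the optimal RMSD rounded to 2 decimals, which makes every cost an
    exact multiple of 0.01 and the cost model rational.
    """
    pa = _as_points(p)
    qa = _as_points(q)
    if pa.shape[0] != qa.shape[0]:
        return big
    return round(_kabsch(pa, qa).rmsd, 2)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (via QR of a Gaussian)."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
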