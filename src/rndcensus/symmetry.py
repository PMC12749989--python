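"""C3 axis estimation, symmetry expansion and Kabsch superposition.

Symmetry expansion mirrors the single-particle-analysis operation: each
trimer is triplicated and each copy rotated about the (pseudo-)three-fold
axis so that all three protomers land at the same position, enabling
per-protomer classification downstream.  All operations are coordinate-space
only; no density volumes are involved.

Conventions: the axis direction is chosen so that the rotation carrying
chain 0 onto chain 1 is a *positive* (counter-clockwise, right-hand-rule)
rotation about ``axis_direction`` — i.e. the three chains appear in
counter-clockwise order viewed down the +axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_model import ChainModel, StructureModel

_ORTHO_TOL = 1e-9


class CorrespondenceError(ValueError):
    """Too few corresponding atoms to superpose."""


@dataclass
class RigidTransform:
    """Proper rigid-body map x ↦ R·x + t."""

    rotation: np.ndarray     # (3,3), det = +1
    translation: np.ndarray  # (3,), Å

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")
        if not np.allclose(
            self.rotation.T @ self.rotation, np.eye(3), atol=1e-6
        ):
            raise ValueError("rotation must be orthogonal")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class SymmetryFrame:
    """A rotational symmetry axis: point on axis, unit direction, order."""

    axis_point: np.ndarray
    axis_direction: np.ndarray
    order: int = 3
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.axis_point = np.asarray(self.axis_point, float)
        d = np.asarray(self.axis_direction, float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("axis direction must be nonzero")
        self.axis_direction = d / n
        if self.order < 2:
            raise ValueError("symmetry order must be ≥ 2")


def rotation_about_axis(
    axis_point: np.ndarray, axis_direction: np.ndarray, angle_deg: float
) -> RigidTransform:
    """Rigid rotation by ``angle_deg`` about the line through axis_point."""
    u = np.asarray(axis_direction, float)
    u = u / np.linalg.norm(u)
    th = np.deg2rad(angle_deg)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
    p = np.asarray(axis_point, float)
    return RigidTransform(R, p - R @ p)


def rotation_axis_angle(R: np.ndarray) -> tuple[np.ndarray, float]:
    """Axis (unit) and angle in degrees of a proper rotation.

    The angle is in [0, 180]; for angle 0 the axis is arbitrary (z is
    returned).  Uses the antisymmetric part for the axis and the trace
    formula (argument clamped to [−1, 1]) for the angle.
    """
    R = np.asarray(R, float)
    cos_th = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = np.degrees(np.arccos(cos_th))
    v = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    n = np.linalg.norm(v)
    if n < 1e-12:
        if cos_th > 0:  # identity
            return np.array([0.0, 0.0, 1.0]), 0.0
        # 180° rotation: axis from the symmetric part
        M = (R + np.eye(3)) / 2.0
        axis = M[:, int(np.argmax(np.diag(M)))]
        return axis / np.linalg.norm(axis), 180.0
    return v / n, float(angle)


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares proper rotation+translation mapping points P onto Q.

    Returns the transform and the post-fit RMSD.  A reflection is never
    returned: if the best orthogonal map is improper, the smallest singular
    direction is flipped (standard Kabsch determinant correction).
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (N, 3) arrays")
    if len(P) < 3:
        raise CorrespondenceError(f"need ≥3 correspondences, got {len(P)}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd


def _chain_correspondence(
    mobile: ChainModel,
    target: ChainModel,
    selection: str = "ca",
) -> tuple[np.ndarray, np.ndarray]:
    """Paired coordinate arrays for the shared atoms of two chains.

    ``ca``: shared residue numbers, Cα atoms only.  ``all_atom``: shared
    (residue_number, atom_name) heavy-atom pairs.  Deterministic: pairs are
    ordered by residue number (then atom name).
    """
    if selection == "ca":
        m, t = mobile.ca_map(), target.ca_map()
        keys = sorted(set(m) & set(t))
    elif selection == "all_atom":
        m, t = mobile.atom_map(), target.atom_map()
        keys = sorted(set(m) & set(t))
    else:
        raise ValueError(f"unknown selection policy {selection!r}")
    if not keys:
        raise CorrespondenceError(
            f"chains {mobile.chain_id!r}/{target.chain_id!r} share no atoms "
            f"under policy {selection!r}"
        )
    return np.array([m[k] for k in keys]), np.array([t[k] for k in keys])


def kabsch_superpose(
    mobile: StructureModel,
    target: StructureModel,
    selection: str = "ca",
    chain_map: dict[str, str] | None = None,
) -> tuple[RigidTransform, float, int]:
    """Superpose ``mobile`` onto ``target``; returns (transform, rmsd Å, n_atoms).

    ``chain_map`` maps mobile chain ids to target chain ids; by default
    chains are paired positionally (first with first, ...).
    """
    if chain_map is None:
        chain_map = {
            mc.chain_id: tc.chain_id
            for mc, tc in zip(mobile.chains, target.chains)
        }
    Ps, Qs = [], []
    for m_id, t_id in chain_map.items():
        P, Q = _chain_correspondence(
            mobile.chain(m_id), target.chain(t_id), selection
        )
        Ps.append(P)
        Qs.append(Q)
    P = np.vstack(Ps)
    Q = np.vstack(Qs)
    if len(P) < 3:
        raise CorrespondenceError(f"need ≥3 correspondences, got {len(P)}")
    tf, rmsd = kabsch(P, Q)
    return tf, rmsd, len(P)


def rmsd_between(
    a: StructureModel,
    b: StructureModel,
    selection: str = "ca",
    chain_map: dict[str, str] | None = None,
    superpose: bool = True,
) -> float:
    """Convenience: RMSD between two models, optionally after superposition."""
    if superpose:
        _, rmsd, _ = kabsch_superpose(a, b, selection, chain_map)
        return rmsd
    if chain_map is None:
        chain_map = {
            mc.chain_id: tc.chain_id for mc, tc in zip(a.chains, b.chains)
        }
    Ps, Qs = [], []
    for m_id, t_id in chain_map.items():
        P, Q = _chain_correspondence(a.chain(m_id), b.chain(t_id), selection)
        Ps.append(P)
        Qs.append(Q)
    P, Q = np.vstack(Ps), np.vstack(Qs)
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Axis estimation and symmetry expansion
# ---------------------------------------------------------------------------

def _chain_centroid(chain: ChainModel) -> np.ndarray:
    return np.array([p for p in chain.ca_map().values()]).mean(axis=0)


def estimate_symmetry_axis(
    trimer: StructureModel,
    chain_triplet: tuple[str, str, str],
    angle_tolerance: float = 15.0,
) -> SymmetryFrame:
    """Estimate the pseudo-C3 axis of a trimer from its three chains.

    The axis point is the centroid of the three chain centroids; the axis
    direction is the rotation axis of the best proper rotation mapping chain
    0 onto chain 1 (sign such that this rotation is counter-clockwise about
    the +axis).  If that rotation's angle deviates from 120° by more than
    ``angle_tolerance`` degrees, a pseudo-symmetry-violation warning is
    attached to the returned frame.
    """
    chains = [trimer.chain(c) for c in chain_triplet]
    # correspondence between chain 0 and chain 1 via shared (resnum, CA)
    P, Q = _chain_correspondence(chains[0], chains[1], "ca")
    if len(P) < 3:
        raise CorrespondenceError(
            f"chains {chain_triplet[0]!r}/{chain_triplet[1]!r} share "
            f"only {len(P)} atoms"
        )
    tf, _ = kabsch(P, Q)
    axis, angle = rotation_axis_angle(tf.rotation)
    point = np.mean([_chain_centroid(c) for c in chains], axis=0)
    warnings = []
    expected = 360.0 / 3
    if abs(angle - expected) > angle_tolerance:
        warnings.append(
            f"pseudo-symmetry violation: chain0→chain1 rotation angle "
            f"{angle:.1f}° deviates from {expected:.0f}° by more than "
            f"{angle_tolerance:.0f}°"
        )
    return SymmetryFrame(point, axis, order=3, warnings=warnings)


@dataclass
class MonomerExtract:
    """One symmetry-expanded protomer in the common frame."""

    structure: StructureModel
    particle_id: str
    copy_index: int


def symmetry_expand(
    trimer: StructureModel,
    frame: SymmetryFrame,
    chain_triplet: tuple[str, ...],
) -> list[MonomerExtract]:
    """Rotate each chain k by −k·(360/order)° about the axis into a common frame.

    For an exactly symmetric trimer the three outputs coincide.  Each output
    carries (particle_id, copy_index) tags, copy_index = 0, 1, 2.
    """
    if frame.order != len(chain_triplet):
        raise ValueError(
            f"frame order {frame.order} ≠ number of chains {len(chain_triplet)}"
        )
    step = 360.0 / frame.order
    out = []
    for k, chain_id in enumerate(chain_triplet):
        tf = rotation_about_axis(frame.axis_point, frame.axis_direction, -k * step)
        chain = trimer.chain(chain_id)
        sub = StructureModel(
            f"{trimer.model_id}_{k}", [chain], dict(trimer.metadata)
        )
        moved = sub.transformed(tf.rotation, tf.translation)
        out.append(MonomerExtract(moved, trimer.model_id, k))
    return out
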