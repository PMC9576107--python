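"""Screw twists and instantaneous screw axes from rigid-body pose sequences.

The relative motion of one segment with respect to another is described by a
sequence of homogeneous transforms T(t) in SE(3).  The screw twist of the
motion is the pair (omega, v0): the angular velocity vector and the
translational velocity of the body-fixed point that instantaneously coincides
with the origin of the reference coordinate system.  It is recovered from two
consecutive poses through the matrix logarithm of the pose difference

    [[omega]_x  v0]
    [[0 0 0]    0 ]  =  logm(T_{k+1} T_k^-1) / dt.

By the Mozzi-Chasles theorem every twist with nonzero angular velocity defines
a unique line in space, the instantaneous screw axis (ISA): direction
n = omega/||omega||, and the point on the line closest to the reference origin
S = omega x v0 / ||omega||^2.

This module also provides the undirected line-comparison metrics (axis angle,
common-normal distance, position-point distance) used throughout the
dispersion and sensitivity analyses.  Internal units are SI (m, rad, s);
distances are reported in mm and angles in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import logm

from .exceptions import BranchCutError, ValidationError

__all__ = [
    "Pose",
    "PoseSequence",
    "ScrewTwist",
    "TwistSequence",
    "ScrewAxis",
    "skew",
    "twist_from_pose_pair",
    "twists_from_sequence",
    "isa_from_twist",
    "axis_angle",
    "common_normal_distance",
    "point_distance",
]

#: Rotations with angle >= pi - _BRANCH_TOL rad are rejected (log branch cut).
_BRANCH_TOL = 1e-6

#: Default angular-speed threshold (rad/s) below which a per-sample ISA is
#: flagged undefined.  Never used by the ASA estimator itself.
DEFAULT_OMEGA_TOL = 1e-8


def _check_rotation(R: np.ndarray, tol: float = 1e-9) -> None:
    if np.linalg.norm(R.T @ R - np.eye(3)) > tol:
        raise ValidationError("rotation block is not orthonormal")
    if abs(np.linalg.det(R) - 1.0) > tol:
        raise ValidationError("rotation block has det != +1")


@dataclass(frozen=True)
class Pose:
    """A time-stamped rigid-body pose as a 4x4 homogeneous transform."""

    t: float
    T: np.ndarray

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        if T.shape != (4, 4):
            raise ValidationError("pose transform must be 4x4")
        if not np.array_equal(T[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValidationError("pose bottom row must be [0, 0, 0, 1]")
        _check_rotation(T[:3, :3])
        object.__setattr__(self, "T", T)

    @property
    def R(self) -> np.ndarray:
        return self.T[:3, :3]

    @property
    def p(self) -> np.ndarray:
        return self.T[:3, 3]


@dataclass(frozen=True)
class PoseSequence:
    """Uniformly sampled sequence of relative poses (length >= 2)."""

    poses: tuple[Pose, ...]
    dt: float

    def __post_init__(self) -> None:
        poses = tuple(self.poses)
        if len(poses) < 2:
            raise ValidationError("pose sequence needs at least 2 samples")
        times = np.array([p.t for p in poses])
        diffs = np.diff(times)
        if np.any(diffs <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        if np.max(np.abs(diffs - self.dt)) > 1e-9:
            raise ValidationError("sampling is not uniform at the nominal dt")
        object.__setattr__(self, "poses", poses)

    def __len__(self) -> int:
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)

    @property
    def times(self) -> np.ndarray:
        return np.array([p.t for p in self.poses])

    @classmethod
    def from_transforms(cls, transforms, dt: float, t0: float = 0.0) -> "PoseSequence":
        """Build a sequence from an iterable of 4x4 arrays sampled at dt."""
        poses = tuple(
            Pose(t=t0 + k * dt, T=np.asarray(T, dtype=float))
            for k, T in enumerate(transforms)
        )
        return cls(poses=poses, dt=dt)


@dataclass(frozen=True)
class ScrewTwist:
    """Screw twist (omega [rad/s], v0 [m/s]) in the reference coordinates."""

    omega: np.ndarray
    v0: np.ndarray

    def __post_init__(self) -> None:
        omega = np.asarray(self.omega, dtype=float).reshape(3)
        v0 = np.asarray(self.v0, dtype=float).reshape(3)
        if not (np.all(np.isfinite(omega)) and np.all(np.isfinite(v0))):
            raise ValidationError("twist components must be finite")
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "v0", v0)


@dataclass(frozen=True)
class TwistSequence:
    """Twists of consecutive pose pairs, stamped at the pair midpoints."""

    twists: tuple[ScrewTwist, ...]
    times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        twists = tuple(self.twists)
        times = (
            np.arange(len(twists), dtype=float)
            if self.times is None
            else np.asarray(self.times, dtype=float)
        )
        if len(times) != len(twists):
            raise ValidationError("times and twists must have equal length")
        object.__setattr__(self, "twists", twists)
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return len(self.twists)

    def __iter__(self):
        return iter(self.twists)

    @property
    def omegas(self) -> np.ndarray:
        """(N, 3) array of angular velocities."""
        return np.array([tw.omega for tw in self.twists])

    @property
    def v0s(self) -> np.ndarray:
        """(N, 3) array of origin-point translational velocities."""
        return np.array([tw.v0 for tw in self.twists])


@dataclass(frozen=True)
class ScrewAxis:
    """A directed line: unit direction n and a point S on the line (m).

    ``defined`` is False when the underlying angular velocity was too small
    for the direction to be meaningful; n and S are then NaN.
    """

    n: np.ndarray
    S: np.ndarray
    defined: bool = True

    def __post_init__(self) -> None:
        n = np.asarray(self.n, dtype=float).reshape(3)
        S = np.asarray(self.S, dtype=float).reshape(3)
        if self.defined and abs(np.linalg.norm(n) - 1.0) > 1e-12:
            raise ValidationError("axis direction must be a unit vector")
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "S", S)

    @classmethod
    def undefined(cls) -> "ScrewAxis":
        return cls(n=np.full(3, np.nan), S=np.full(3, np.nan), defined=False)


def skew(v) -> np.ndarray:
    """Skew-symmetric cross-product matrix: skew(v) @ w == cross(v, w)."""
    x, y, z = np.asarray(v, dtype=float).reshape(3)
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


def _rotation_angle(R: np.ndarray) -> float:
    return float(np.arccos(np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)))


def twist_from_pose_pair(T_k: Pose, T_k1: Pose, dt: float) -> ScrewTwist:
    """Screw twist from two consecutive poses via the SE(3) matrix log.

    Uses the spatial convention dT = T_{k+1} T_k^-1, so (omega, v0) are
    expressed in the same (reference) coordinate system as the poses and v0
    is the velocity of the body point at the reference origin.

    Raises
    ------
    BranchCutError
        If the relative rotation angle is within 1e-6 rad of pi.
    """
    if dt <= 0:
        raise ValidationError("dt must be positive")
    dT = T_k1.T @ np.linalg.inv(T_k.T)
    if _rotation_angle(dT[:3, :3]) >= np.pi - _BRANCH_TOL:
        raise BranchCutError("matrix log near branch cut (rotation angle ~ pi)")
    L = logm(dT)
    L = np.real(L) / dt
    W = (L[:3, :3] - L[:3, :3].T) / 2.0  # symmetrize away rounding residue
    omega = np.array([W[2, 1], W[0, 2], W[1, 0]])
    return ScrewTwist(omega=omega, v0=L[:3, 3])


def twists_from_sequence(ps: PoseSequence) -> TwistSequence:
    """Twists of all consecutive pose pairs, stamped at pair midpoints."""
    twists = []
    times = []
    for k in range(len(ps) - 1):
        a, b = ps.poses[k], ps.poses[k + 1]
        try:
            twists.append(twist_from_pose_pair(a, b, ps.dt))
        except BranchCutError as err:
            raise BranchCutError(f"{err} at pose pair index {k}") from err
        times.append(0.5 * (a.t + b.t))
    return TwistSequence(twists=tuple(twists), times=np.array(times))


def isa_from_twist(tw: ScrewTwist, omega_tol: float = DEFAULT_OMEGA_TOL) -> ScrewAxis:
    """Instantaneous screw axis of a twist.

    n = omega/||omega||; S = omega x v0 / ||omega||^2 is the point on the
    axis closest to the reference origin (so S . n = 0).  When
    ||omega|| <= omega_tol the direction is ill-defined and an undefined
    axis is returned instead of raising; the flag only matters for
    per-sample ISA reporting, never for ASA estimation.
    """
    w = np.linalg.norm(tw.omega)
    if w <= omega_tol:
        return ScrewAxis.undefined()
    n = tw.omega / w
    S = np.cross(tw.omega, tw.v0) / w**2
    return ScrewAxis(n=n, S=S)


def axis_angle(a: ScrewAxis, b: ScrewAxis) -> float:
    """Undirected angle between two axis directions, in degrees [0, 90]."""
    if not (a.defined and b.defined):
        raise ValidationError("both axes must be defined")
    c = np.clip(abs(float(np.dot(a.n, b.n))), 0.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def common_normal_distance(a: ScrewAxis, b: ScrewAxis) -> float:
    """Length of the common normal segment between two lines, in mm.

    For skew or intersecting lines this is |(S_b - S_a) . (n_a x n_b)| /
    ||n_a x n_b||; for (anti)parallel lines it degrades to the perpendicular
    point-line distance.
    """
    if not (a.defined and b.defined):
        raise ValidationError("both axes must be defined")
    d = b.S - a.S
    cr = np.cross(a.n, b.n)
    ncr = np.linalg.norm(cr)
    if ncr < 1e-9:  # parallel
        perp = d - np.dot(d, a.n) * a.n
        return 1e3 * float(np.linalg.norm(perp))
    return 1e3 * float(abs(np.dot(d, cr)) / ncr)


def point_distance(a: ScrewAxis, b: ScrewAxis) -> float:
    """Euclidean distance between the two axis position points, in mm."""
    if not (a.defined and b.defined):
        raise ValidationError("both axes must be defined")
    return 1e3 * float(np.linalg.norm(a.S - b.S))
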