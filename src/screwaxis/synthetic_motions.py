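"""Synthetic joint motions and SE(3) pose-noise injection.

Three generators:

* ``generate_cylindrical`` — the ideal cylindrical (purely rotational) joint:
  segment 2 swings about a fixed geometric axis (GA) with angle
  alpha(t) = A sin(2 pi t / T) + U.  Its origin rides a circle of radius r
  centered on the axis, its y-axis points at the rotation center, its z-axis
  is the rotation axis.  Every instantaneous screw axis of this motion
  coincides exactly with the GA, which makes the sequence the reference
  ground truth for estimator and dispersion tests.  Defaults: axis (0,0,1)
  through (0, -0.25, 0) m, r = 0.25 m, A = 45 deg, U = 180 deg, T = 1 s,
  one period sampled at 100 Hz, endpoint inclusive.

* ``generate_hinge_swing`` — a damped sinusoidal rotation about an arbitrary
  fixed axis, a surrogate for the free swing of a physical hinge.

* ``generate_ball_swing`` — rotation about a center with a time-varying axis
  direction; gives well-conditioned (full-rank) pseudo-intersection problems
  for property tests.

``add_pose_noise`` perturbs each pose by right-multiplication with
expm of an se(3) element whose rotation part has fixed magnitude (the stated
noise level in degrees) and uniformly random direction, and likewise for the
translation part — so "3 deg / 2 mm" are exact perturbation magnitudes, not
distribution scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .screw_kinematics import Pose, PoseSequence, ScrewAxis, skew

__all__ = [
    "CylindricalJointConfig",
    "NoiseSpec",
    "generate_cylindrical",
    "add_pose_noise",
    "generate_hinge_swing",
    "generate_ball_swing",
]


def _rotation_about(n: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about unit axis n."""
    K = skew(n)
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def _orthonormal_basis(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing n to a right-handed triad (e1, e2, n).

    For n = (0,0,1) returns exactly the global x and y axes, so the default
    cylindrical-joint configuration reduces to the canonical planar case.
    """
    n = n / np.linalg.norm(n)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, n)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = seed - np.dot(seed, n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


@dataclass(frozen=True)
class CylindricalJointConfig:
    """Ideal cylindrical joint parameters (defaults = reference conditions)."""

    n_GA: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    S_GA: np.ndarray = field(default_factory=lambda: np.array([0.0, -0.25, 0.0]))
    r: float = 0.25  # m
    A: float = 45.0  # swing amplitude, deg
    U: float = 180.0  # swing offset, deg
    T: float = 1.0  # swing period, s
    duration: float = 1.0  # s
    fs: float = 100.0  # Hz
    endpoint_inclusive: bool = True

    def __post_init__(self) -> None:
        if self.r <= 0 or self.T <= 0 or self.fs <= 0 or self.duration <= 0:
            raise ValidationError("r, T, fs and duration must be positive")
        n = np.asarray(self.n_GA, dtype=float).reshape(3)
        object.__setattr__(self, "n_GA", n / np.linalg.norm(n))
        object.__setattr__(self, "S_GA", np.asarray(self.S_GA, dtype=float).reshape(3))


@dataclass(frozen=True)
class NoiseSpec:
    """Fixed-magnitude random pose perturbation: rotation deg, translation mm."""

    rot_level: float = 0.0  # deg
    trans_level: float = 0.0  # mm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rot_level < 0 or self.trans_level < 0:
            raise ValidationError("noise levels must be >= 0")


def generate_cylindrical(cfg: CylindricalJointConfig | None = None) -> PoseSequence:
    """Pose sequence of the ideal cylindrical joint.

    At each sample, alpha = A sin(2 pi t / T) + U (degrees); the segment-2
    origin is S_GA + r (cos(alpha) e1 + sin(alpha) e2) with (e1, e2)
    spanning the rotation plane, the y-axis of segment 2 points from the
    origin toward the rotation center S_GA, the z-axis is n_GA, and the
    x-axis completes the right-handed frame.  The motion is then a pure
    rotation about the line (n_GA, S_GA): every ISA lies exactly on it.
    """
    cfg = cfg or CylindricalJointConfig()
    dt = 1.0 / cfg.fs
    n_steps = int(round(cfg.duration * cfg.fs))
    n_samples = n_steps + 1 if cfg.endpoint_inclusive else n_steps
    e1, e2 = _orthonormal_basis(cfg.n_GA)
    transforms = []
    for k in range(n_samples):
        t = k * dt
        alpha = np.deg2rad(cfg.A) * np.sin(2.0 * np.pi * t / cfg.T) + np.deg2rad(cfg.U)
        offset = cfg.r * (np.cos(alpha) * e1 + np.sin(alpha) * e2)
        if np.linalg.norm(offset) < 1e-12:
            raise ValidationError(f"degenerate configuration at t={t}")
        O = cfg.S_GA + offset
        j = -offset / np.linalg.norm(offset)  # toward the rotation center
        kz = cfg.n_GA
        i = np.cross(j, kz)
        T = np.eye(4)
        T[:3, 0] = i
        T[:3, 1] = j
        T[:3, 2] = kz
        T[:3, 3] = O
        transforms.append(T)
    return PoseSequence.from_transforms(transforms, dt=dt)


def _se3_exp(rho: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Closed-form exp of the se(3) element (rotation vector rho, translation d).

    Matches expm([[skew(rho), d], [0, 0]]): the translation column is
    V(rho) d with the standard left-Jacobian V.
    """
    theta = np.linalg.norm(rho)
    K = skew(rho)
    T = np.eye(4)
    if theta < 1e-12:
        T[:3, 3] = d
        return T
    K2 = K @ K
    R = np.eye(3) + (np.sin(theta) / theta) * K + ((1 - np.cos(theta)) / theta**2) * K2
    V = (
        np.eye(3)
        + ((1 - np.cos(theta)) / theta**2) * K
        + ((theta - np.sin(theta)) / theta**3) * K2
    )
    T[:3, :3] = R
    T[:3, 3] = V @ d
    return T


def _uniform_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def add_pose_noise(ps: PoseSequence, spec: NoiseSpec) -> PoseSequence:
    """Right-multiply each pose by a fixed-magnitude random SE(3) perturbation.

    The rotation perturbation vector has norm rot_level (converted to rad)
    and uniformly random direction; the translation argument has norm
    trans_level (converted to m) and independent uniform direction.  Fresh
    draws per sample; fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rot = np.deg2rad(spec.rot_level)
    trans = 1e-3 * spec.trans_level
    poses = []
    for p in ps.poses:
        rho = rot * _uniform_unit_vector(rng)
        d = trans * _uniform_unit_vector(rng)
        poses.append(Pose(t=p.t, T=p.T @ _se3_exp(rho, d)))
    return PoseSequence(poses=tuple(poses), dt=ps.dt)


def generate_hinge_swing(
    axis: ScrewAxis,
    amplitude_deg: float = 45.0,
    period_s: float = 1.0,
    damping_ratio: float = 0.0,
    duration_s: float = 1.0,
    fs: float = 100.0,
) -> PoseSequence:
    """Damped sinusoidal rotation about a fixed axis (free-swing surrogate).

    theta(t) = A exp(-zeta * w0 * t) sin(w0 t) with w0 = 2 pi / period.
    All twists of the sequence are parallel to axis.n and every ISA lies on
    the given axis line.
    """
    dt = 1.0 / fs
    w0 = 2.0 * np.pi / period_s
    A = np.deg2rad(amplitude_deg)
    n = axis.n / np.linalg.norm(axis.n)
    n_samples = int(round(duration_s * fs)) + 1
    transforms = []
    for k in range(n_samples):
        t = k * dt
        theta = A * np.exp(-damping_ratio * w0 * t) * np.sin(w0 * t)
        R = _rotation_about(n, theta)
        T = np.eye(4)
        T[:3, :3] = R
        T[:3, 3] = axis.S - R @ axis.S  # rotation about the line through axis.S
        transforms.append(T)
    return PoseSequence.from_transforms(transforms, dt=dt)


def generate_ball_swing(
    center=(0.0, 0.0, 0.0),
    cone_half_angle_deg: float = 30.0,
    amplitude_deg: float = 40.0,
    period_s: float = 1.0,
    duration_s: float = 1.0,
    fs: float = 100.0,
) -> PoseSequence:
    """Ball-and-socket-like motion: rotation about a center with a wobbling axis.

    The rotation axis direction sweeps a cone of the given half-angle around
    z while the rotation angle oscillates sinusoidally, so the angular
    velocities span all three directions and the pseudo-intersection problem
    is well conditioned; every ISA passes through ``center``.
    """
    center = np.asarray(center, dtype=float).reshape(3)
    dt = 1.0 / fs
    beta = np.deg2rad(cone_half_angle_deg)
    A = np.deg2rad(amplitude_deg)
    n_samples = int(round(duration_s * fs)) + 1
    transforms = []
    for k in range(n_samples):
        t = k * dt
        phi = 2.0 * np.pi * t / period_s
        axis_dir = np.array(
            [np.sin(beta) * np.cos(phi), np.sin(beta) * np.sin(phi), np.cos(beta)]
        )
        theta = A * np.sin(2.0 * np.pi * t / period_s)
        R = _rotation_about(axis_dir, theta)
        T = np.eye(4)
        T[:3, :3] = R
        T[:3, 3] = center - R @ center
        transforms.append(T)
    return PoseSequence.from_transforms(transforms, dt=dt)
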