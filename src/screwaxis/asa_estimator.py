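"""Average screw axis (ASA) estimation from a batch of screw twists.

The ASA is the line closest and most parallel to the set of instantaneous
screw axes of a motion.  Its direction is the unit vector most parallel to
all angular velocities,

    n_asa = argmax_n (1/N) sum_i (omega_i . n)^2,   ||n|| = 1,

which is the dominant eigenvector of the (non-mean-centered) second-moment
matrix C_omega = (1/N) sum_i omega_i omega_i^T.  Weighting each sample by the
angular-speed magnitude is what removes the need for the customary ~0.3 rad/s
angular-velocity threshold: slow, ill-defined samples simply contribute
little.

The position is the velocity-weighted pseudo-intersection of the ISAs — the
point with the smallest mean squared residual velocity — regularized toward a
prior point S0 (typically the geometric joint center) with weight epsilon:

    S_asa = ((1/N) sum_i K_i K_i^T + eps I)^-1 ((1/N) sum_i K_i v0_i + eps S0),

with K_i = skew(omega_i).  With eps = 0 this is plain least squares; for
hinge-like motion the normal matrix is rank-deficient (the position is
undefined along the axis) and the minimum-norm solution is returned together
with a rank flag and the null direction.

A right-handed coordinate frame is attached to the ASA: x along n_asa,
y along the eigenvector of the smallest eigenvalue of C_omega (the normal to
the plane containing most of the ISA variation), z completing the frame,
origin at S_asa.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InsufficientDataError, UndefinedAxisError
from .screw_kinematics import PoseSequence, ScrewAxis, TwistSequence, twists_from_sequence

__all__ = [
    "AsaConfig",
    "AngularCovariance",
    "PositionSolution",
    "AsaResult",
    "angular_covariance",
    "asa_direction",
    "asa_position",
    "asa_frame",
    "estimate_asa",
]

#: Condition number beyond which the unregularized normal matrix is treated
#: as rank-deficient and solved in the minimum-norm sense.
RANK_DEFICIENT_COND = 1e12


@dataclass(frozen=True)
class AsaConfig:
    """Estimator configuration.

    Parameters
    ----------
    epsilon
        Regularization weight balancing ||S - S0||^2 (m^2) against the mean
        squared residual velocity (m^2/s^2); units 1/s^2.  Default 0.01.
        Set to 0 for the unregularized least-squares position.
    S0
        Prior point for the position, in meters.  Should approximate the
        geometric joint center when known; defaults to the origin of the
        reference coordinate system.
    alpha
        Confidence level used for downstream dispersion ellipsoids.
    """

    epsilon: float = 0.01
    S0: np.ndarray = field(default_factory=lambda: np.zeros(3))
    alpha: float = 0.95

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        object.__setattr__(self, "S0", np.asarray(self.S0, dtype=float).reshape(3))


@dataclass(frozen=True)
class AngularCovariance:
    """Second-moment matrix C = (1/N) sum omega_i omega_i^T  [rad^2/s^2]."""

    C: np.ndarray
    N: int

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if np.linalg.norm(C - C.T) > 1e-12:
            raise ValueError("covariance must be symmetric")
        if np.min(np.linalg.eigvalsh(C)) < -1e-12:
            raise ValueError("covariance must be positive semi-definite")
        object.__setattr__(self, "C", C)

    @property
    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues in decreasing order."""
        return np.linalg.eigvalsh(self.C)[::-1]


@dataclass(frozen=True)
class PositionSolution:
    """Outcome of the position solve.

    ``regularized`` records whether the epsilon-regularized system was used;
    ``rank_deficient`` flags a (near-)singular unregularized normal matrix, in
    which case ``S`` is the minimum-norm solution and ``null_direction`` spans
    the unresolved direction (the position is unbounded along it).
    """

    S: np.ndarray
    regularized: bool
    rank_deficient: bool = False
    null_direction: np.ndarray | None = None


def angular_covariance(tws: TwistSequence) -> AngularCovariance:
    """C_omega = (1/N) sum_i omega_i omega_i^T over all twists."""
    if len(tws) == 0:
        raise InsufficientDataError("no twists")
    W = tws.omegas
    C = W.T @ W / len(tws)
    C = (C + C.T) / 2.0
    return AngularCovariance(C=C, N=len(tws))


def _signed_eigvec(v: np.ndarray, reference: np.ndarray | None) -> np.ndarray:
    """Resolve the eigenvector sign: along ``reference`` when available,
    else largest-magnitude component positive."""
    if reference is not None:
        d = float(np.dot(v, reference))
        if abs(d) >= 1e-12:
            return v if d > 0 else -v
    i = int(np.argmax(np.abs(v)))
    return v if v[i] > 0 else -v


def asa_direction(C: AngularCovariance, mean_omega) -> np.ndarray:
    """Dominant eigenvector of C_omega, sign-aligned with the mean omega."""
    lam, U = np.linalg.eigh(C.C)
    if lam[-1] < 1e-15:
        raise UndefinedAxisError("direction undefined: all angular velocities ~ zero")
    n = U[:, -1]
    n = n / np.linalg.norm(n)
    return _signed_eigvec(n, np.asarray(mean_omega, dtype=float))


def asa_position(tws: TwistSequence, config: AsaConfig) -> PositionSolution:
    """Regularized least-squares pseudo-intersection of the ISAs.

    Solves (A + eps I) S = b + eps S0 with A = (1/N) sum K_i K_i^T and
    b = (1/N) sum K_i v0_i (K_i = skew(omega_i)).  With eps = 0 and a
    rank-deficient A the minimum-norm solution is returned and flagged.
    """
    if len(tws) == 0:
        raise InsufficientDataError("no twists")
    W = tws.omegas
    V = tws.v0s
    N = len(tws)
    # K K^T = ||w||^2 I - w w^T ;  K v0 = w x v0
    A = float(np.mean(np.sum(W**2, axis=1))) * np.eye(3) - W.T @ W / N
    A = (A + A.T) / 2.0
    b = np.mean(np.cross(W, V), axis=0)
    if config.epsilon > 0:
        S = np.linalg.solve(A + config.epsilon * np.eye(3), b + config.epsilon * config.S0)
        return PositionSolution(S=S, regularized=True)
    lam, U = np.linalg.eigh(A)
    if lam[-1] < 1e-15:
        raise UndefinedAxisError("position undefined: all angular velocities ~ zero")
    cond = np.inf if lam[0] <= 0 else float(lam[-1] / lam[0])
    if cond > RANK_DEFICIENT_COND:
        keep = lam > lam[-1] / RANK_DEFICIENT_COND
        S = U[:, keep] @ ((U[:, keep].T @ b) / lam[keep])
        null = _signed_eigvec(U[:, 0], None)
        return PositionSolution(S=S, regularized=False, rank_deficient=True, null_direction=null)
    S = np.linalg.solve(A, b)
    return PositionSolution(S=S, regularized=False)


def asa_frame(n_asa, S_asa, C: AngularCovariance) -> np.ndarray:
    """Right-handed homogeneous frame attached to the ASA.

    Column 1 is n_asa; column 2 is the eigenvector of the smallest eigenvalue
    of C_omega (normal to the plane of largest ISA variation), re-orthogonalized
    against column 1 if floating-point drift left them non-orthogonal; column 3
    completes the right-handed triad; the origin is S_asa.
    """
    n = np.asarray(n_asa, dtype=float).reshape(3)
    S = np.asarray(S_asa, dtype=float).reshape(3)
    lam, U = np.linalg.eigh(C.C)
    e2 = _signed_eigvec(U[:, 0] / np.linalg.norm(U[:, 0]), None)
    if abs(np.dot(n, e2)) > 1e-9:
        e2 = e2 - np.dot(e2, n) * n
        e2 = _signed_eigvec(e2 / np.linalg.norm(e2), None)
    e3 = np.cross(n, e2)
    T = np.eye(4)
    T[:3, 0] = n
    T[:3, 1] = e2
    T[:3, 2] = e3
    T[:3, 3] = S
    return T


@dataclass(frozen=True)
class AsaResult:
    """Full output of the ASA estimation pipeline."""

    axis: ScrewAxis
    frame: np.ndarray
    cov_omega: AngularCovariance
    config: AsaConfig
    regularized: bool
    rank_deficient: bool = False
    null_direction: np.ndarray | None = None
    twists: TwistSequence | None = None

    def to_dict(self) -> dict:
        """JSON-ready summary (axis in m and mm, frame, flags, eigenvalues)."""
        return {
            "n_asa": self.axis.n.tolist(),
            "S_asa_m": self.axis.S.tolist(),
            "S_asa_mm": (1e3 * self.axis.S).tolist(),
            "frame": self.frame.tolist(),
            "epsilon": self.config.epsilon,
            "S0_m": self.config.S0.tolist(),
            "alpha": self.config.alpha,
            "regularized": self.regularized,
            "rank_deficient": self.rank_deficient,
            "null_direction": None
            if self.null_direction is None
            else self.null_direction.tolist(),
            "cov_omega_eigenvalues": self.cov_omega.eigenvalues.tolist(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def estimate_asa(ps: PoseSequence, config: AsaConfig | None = None) -> AsaResult:
    """Estimate the ASA of a pose sequence.

    Pipeline: screw twists from consecutive pose pairs -> angular second-moment
    matrix -> dominant-eigenvector direction -> regularized least-squares
    position -> ASA-attached frame.
    """
    config = config or AsaConfig()
    tws = twists_from_sequence(ps)
    C = angular_covariance(tws)
    n = asa_direction(C, np.mean(tws.omegas, axis=0))
    pos = asa_position(tws, config)
    frame = asa_frame(n, pos.S, C)
    return AsaResult(
        axis=ScrewAxis(n=n, S=pos.S),
        frame=frame,
        cov_omega=C,
        config=config,
        regularized=pos.regularized,
        rank_deficient=pos.rank_deficient,
        null_direction=pos.null_direction,
        twists=tws,
    )
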