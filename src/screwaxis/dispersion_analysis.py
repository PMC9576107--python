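"""Dispersion of the instantaneous screw axes about the average screw axis.

The spread of the ISAs — equivalently, the uncertainty of the ASA estimate —
is quantified three ways:

* **Confidence ellipsoids.**  Eigen-decompose a covariance matrix
  C = U diag(lambda) U^T (eigenvalues descending); the i-th ellipsoid
  semi-axis points along u_i with magnitude m_i = gamma * sqrt(lambda_i),
  where gamma = sqrt of the chi-square quantile at confidence alpha with
  3 degrees of freedom (gamma ~ 2.7955 at alpha = 0.95).  Applied to the
  angular-velocity second moment C_omega (rad/s) and to the position
  covariance C_S (mm).

* **Eigenvalue ratios.**  rho1 = (lambda2 + lambda3)/lambda1 measures how
  dominant the principal direction is (0 for a perfect hinge); rho2 =
  lambda3/lambda2 measures how planar the remaining variation is.

* **RMSE metrics.**  The literature's conventional dispersion numbers: the
  RMS undirected angle between each ISA direction and the ASA direction, and
  the RMS perpendicular distance from the ASA position point to each ISA
  line.  Per convention these use only samples above an angular-speed
  threshold (~0.3 rad/s).

The position covariance follows from the regression view of the position
estimate: C_S = sigma^2 [ (1/N) sum K_i K_i^T ]^-1 with the residual variance
estimated as sigma^2 = sum ||omega_i x S_asa + v0_i||^2 / (N (3N - 3)).
Using K K^T = ||omega||^2 I - omega omega^T this is identically
sigma^2 (trace(C_omega) I - C_omega)^-1, so C_S shares the eigenvectors of
C_omega and its dominant-uncertainty direction is the ASA direction itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .exceptions import InsufficientDataError, ValidationError
from .screw_kinematics import ScrewAxis, TwistSequence

__all__ = [
    "EllipsoidSpec",
    "PositionCovariance",
    "DispersionReport",
    "gamma_factor",
    "confidence_ellipsoid",
    "eigenvalue_ratios",
    "sigma2_hat",
    "position_covariance",
    "rmse_dispersion",
]


def gamma_factor(alpha: float, dof: int = 3) -> float:
    """Ellipsoid scale gamma_{alpha,dof} = sqrt(chi2 quantile)."""
    return float(np.sqrt(chi2.ppf(alpha, dof)))


@dataclass(frozen=True)
class EllipsoidSpec:
    """Confidence ellipsoid: principal directions, magnitudes, scale."""

    axes_dirs: np.ndarray  # 3x3, columns in decreasing-eigenvalue order
    magnitudes: np.ndarray  # descending, gamma * sqrt(lambda_i)
    eigenvalues: np.ndarray  # descending
    alpha: float
    gamma: float


@dataclass(frozen=True)
class PositionCovariance:
    """Position covariance C_S [m^2] with a rank-deficiency flag."""

    C: np.ndarray
    rank_deficient: bool


def confidence_ellipsoid(C, alpha: float = 0.95) -> EllipsoidSpec:
    """Confidence ellipsoid of a symmetric PSD covariance matrix.

    Eigenvalues are sorted descending; small negative eigenvalues (rounding)
    are clipped to zero.  Magnitude of axis i is gamma * sqrt(lambda_i).
    """
    C = np.asarray(C, dtype=float)
    if C.shape != (3, 3) or np.linalg.norm(C - C.T) > 1e-9:
        raise ValidationError("covariance must be a symmetric 3x3 matrix")
    lam, U = np.linalg.eigh((C + C.T) / 2.0)
    lam = np.clip(lam[::-1], 0.0, None)
    U = U[:, ::-1]
    g = gamma_factor(alpha)
    return EllipsoidSpec(
        axes_dirs=U,
        magnitudes=g * np.sqrt(lam),
        eigenvalues=lam,
        alpha=alpha,
        gamma=g,
    )


def eigenvalue_ratios(lams) -> tuple[float, float]:
    """(rho1, rho2) = ((l2+l3)/l1, l3/l2) for descending eigenvalues.

    A zero denominator with a numerator that is also numerically zero
    (<= 1e-15 * l1) yields 0; a zero denominator with a significant numerator
    is indeterminate and raises.
    """
    l1, l2, l3 = (float(x) for x in lams)
    if not (l1 >= l2 >= l3 >= -1e-15):
        raise ValidationError("eigenvalues must be sorted descending and >= 0")
    l3 = max(l3, 0.0)
    if l1 <= 0.0:
        return 0.0, 0.0

    def ratio(num: float, den: float) -> float:
        if den > 0:
            return num / den
        if num <= 1e-15 * l1:
            return 0.0
        raise ValidationError("indeterminate eigenvalue ratio (0 denominator)")

    return ratio(l2 + l3, l1), ratio(l3, l2)


def sigma2_hat(tws: TwistSequence, S_asa) -> float:
    """Residual-velocity variance estimate [m^2/s^2].

    sigma^2 = sum_i ||omega_i x S + v0_i||^2 / (N (3N - 3)); needs N >= 2.
    """
    N = len(tws)
    if N < 2:
        raise InsufficientDataError("sigma^2 estimate needs at least 2 twists")
    S = np.asarray(S_asa, dtype=float).reshape(3)
    res = np.cross(tws.omegas, np.broadcast_to(S, (N, 3))) + tws.v0s
    return float(np.sum(res**2) / (N * (3 * N - 3)))


def position_covariance(C_omega, sigma2: float) -> PositionCovariance:
    """C_S = sigma^2 (trace(C_omega) I - C_omega)^-1  [m^2].

    Falls back to the pseudo-inverse (with a flag) when the matrix
    trace(C_omega) I - C_omega is rank-deficient — e.g. for a perfect hinge,
    where the position uncertainty along the axis is unbounded.
    """
    C = np.asarray(getattr(C_omega, "C", C_omega), dtype=float)
    M = np.trace(C) * np.eye(3) - C
    M = (M + M.T) / 2.0
    lam = np.linalg.eigvalsh(M)
    rank_deficient = bool(lam[0] <= 0 or lam[-1] / lam[0] > 1e12)
    if rank_deficient:
        CS = sigma2 * np.linalg.pinv(M, rcond=1e-12, hermitian=True)
    else:
        CS = sigma2 * np.linalg.inv(M)
    return PositionCovariance(C=(CS + CS.T) / 2.0, rank_deficient=rank_deficient)


def rmse_dispersion(isas: list[ScrewAxis], asa: ScrewAxis) -> tuple[float, float]:
    """Conventional (state-of-the-art) RMSE dispersion metrics.

    Returns (rmse_angle_deg, rmse_dist_mm): the RMS undirected angle between
    each defined ISA direction and the ASA direction, and the RMS
    perpendicular distance from the ASA position point to each defined ISA
    line.  Undefined ISAs are excluded; an empty set raises.
    """
    defined = [isa for isa in isas if isa.defined]
    if not defined:
        raise InsufficientDataError("no defined ISAs")
    Nn = np.array([isa.n for isa in defined])
    Ss = np.array([isa.S for isa in defined])
    cosang = np.clip(np.abs(Nn @ asa.n), 0.0, 1.0)
    angles = np.degrees(np.arccos(cosang))
    d = asa.S - Ss
    perp = d - (np.sum(d * Nn, axis=1)[:, None]) * Nn
    dists = 1e3 * np.linalg.norm(perp, axis=1)
    return float(np.sqrt(np.mean(angles**2))), float(np.sqrt(np.mean(dists**2)))


@dataclass(frozen=True)
class DispersionReport:
    """Everything the dispersion analysis produces for one motion."""

    orientation: EllipsoidSpec
    orientation_ratios: tuple[float, float]
    position: EllipsoidSpec
    position_ratios: tuple[float, float]
    C_S: PositionCovariance
    sigma2_hat: float
    rmse_angle_deg: float
    rmse_dist_mm: float
    n_samples: int

    def to_dict(self) -> dict:
        """JSON-ready summary mirroring the direction/position table layout.

        Orientation magnitudes are rad/s; position magnitudes are converted
        to mm (the covariance itself is m^2).
        """
        return {
            "n_samples": self.n_samples,
            "orientation": {
                "ellipsoid_magnitudes_rad_s": self.orientation.magnitudes.tolist(),
                "ellipsoid_axes": self.orientation.axes_dirs.tolist(),
                "eigenvalues": self.orientation.eigenvalues.tolist(),
                "rho1": self.orientation_ratios[0],
                "rho2": self.orientation_ratios[1],
            },
            "position": {
                "ellipsoid_magnitudes_mm": (1e3 * self.position.magnitudes).tolist(),
                "ellipsoid_axes": self.position.axes_dirs.tolist(),
                "eigenvalues_m2": self.position.eigenvalues.tolist(),
                "rho1": self.position_ratios[0],
                "rho2": self.position_ratios[1],
                "rank_deficient": self.C_S.rank_deficient,
            },
            "sigma2_hat_m2_s2": self.sigma2_hat,
            "soa_rmse": {
                "orientation_deg": self.rmse_angle_deg,
                "position_mm": self.rmse_dist_mm,
            },
            "alpha": self.orientation.alpha,
            "gamma": self.orientation.gamma,
        }
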