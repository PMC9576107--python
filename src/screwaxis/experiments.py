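"""Scripted study protocols: regularization effect, noise sensitivity, dispersion.

Also implements the conventional ("state-of-the-art", SoA) average-axis
estimator used as the comparison baseline: per-sample ISAs are kept only when
the angular speed exceeds a threshold (conventionally ~0.3 rad/s); the
average direction is the normalized mean of the sign-aligned unit ISA
directions; the position is the unweighted least-squares pseudo-intersection
of the retained ISA lines.  The contrast with the estimator in
:mod:`screwaxis.asa_estimator` is exactly the velocity-norm weighting (no
threshold) and the regularization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .asa_estimator import AsaConfig, AsaResult, angular_covariance, estimate_asa
from .dispersion_analysis import (
    DispersionReport,
    confidence_ellipsoid,
    eigenvalue_ratios,
    position_covariance,
    rmse_dispersion,
    sigma2_hat,
)
from .exceptions import UndefinedAxisError
from .screw_kinematics import (
    PoseSequence,
    ScrewAxis,
    TwistSequence,
    axis_angle,
    common_normal_distance,
    isa_from_twist,
    point_distance,
    twists_from_sequence,
)
from .synthetic_motions import NoiseSpec, add_pose_noise

__all__ = [
    "SoAConfig",
    "RegularizationReport",
    "SensitivityReport",
    "soa_asa",
    "regularization_study",
    "sensitivity_study",
    "dispersion_study",
]

DEFAULT_EPSILONS = (1e-4, 1e-3, 1e-2, 1e-1)
DEFAULT_NOISE_LEVELS = ((3.0, 2.0), (6.0, 4.0))  # (deg, mm)


@dataclass(frozen=True)
class SoAConfig:
    """Baseline estimator settings: the angular-speed cutoff in rad/s."""

    omega_threshold: float = 0.3

    def __post_init__(self) -> None:
        if self.omega_threshold < 0:
            raise ValueError("threshold must be >= 0")


def soa_asa(tws: TwistSequence, cfg: SoAConfig | None = None) -> ScrewAxis:
    """Threshold-based average screw axis (the literature baseline).

    Only samples with ||omega|| > threshold contribute.  Direction: mean of
    the unit ISA directions after sign-aligning each with the first,
    renormalized.  Position: unweighted pseudo-intersection of the ISA
    lines, i.e. the minimizer of sum ||n_i x S + v0_i/||omega_i||||^2
    (minimum-norm on rank deficiency).
    """
    cfg = cfg or SoAConfig()
    W = tws.omegas
    V = tws.v0s
    speeds = np.linalg.norm(W, axis=1)
    mask = speeds > cfg.omega_threshold
    if not np.any(mask):
        raise UndefinedAxisError("SoA undefined - no samples above threshold")
    Nn = W[mask] / speeds[mask, None]
    signs = np.where(Nn @ Nn[0] < 0, -1.0, 1.0)
    Nn_aligned = signs[:, None] * Nn
    n_mean = Nn_aligned.mean(axis=0)
    norm = np.linalg.norm(n_mean)
    if norm < 1e-15:
        raise UndefinedAxisError("SoA direction undefined: unit directions cancel")
    n = n_mean / norm
    # pseudo-intersection with unit directions: sum (I - n_i n_i^T) S = sum n_i x (v0_i/|w_i|)
    Vu = V[mask] / speeds[mask, None]
    M = len(Nn)
    A = M * np.eye(3) - Nn.T @ Nn
    b = np.sum(np.cross(Nn, Vu), axis=0)
    lam, U = np.linalg.eigh((A + A.T) / 2.0)
    if lam[0] <= 0 or lam[-1] / lam[0] > 1e12:
        keep = lam > lam[-1] / 1e12
        S = U[:, keep] @ ((U[:, keep].T @ b) / lam[keep])
    else:
        S = np.linalg.solve(A, b)
    return ScrewAxis(n=n, S=S)


@dataclass(frozen=True)
class RegularizationRow:
    epsilon: float
    common_normal_mm: float
    point_distance_mm: float  # +inf when the eps=0 position is unbounded
    displacement_direction: np.ndarray | None


@dataclass(frozen=True)
class RegularizationReport:
    """Regularized-vs-unregularized ASA comparison across an epsilon grid."""

    rows: tuple[RegularizationRow, ...]
    baseline: AsaResult  # the eps = 0 estimate
    S0: np.ndarray

    def to_dict(self) -> dict:
        return {
            "S0_m": self.S0.tolist(),
            "baseline_rank_deficient": self.baseline.rank_deficient,
            "rows": [
                {
                    "epsilon": r.epsilon,
                    "common_normal_mm": r.common_normal_mm,
                    "point_distance_mm": r.point_distance_mm,
                    "displacement_direction": None
                    if r.displacement_direction is None
                    else r.displacement_direction.tolist(),
                }
                for r in self.rows
            ],
        }


def regularization_study(
    ps: PoseSequence,
    epsilons=DEFAULT_EPSILONS,
    S0=(0.0, 0.0, 0.0),
) -> RegularizationReport:
    """Compare the regularized ASA against the eps = 0 ASA for each epsilon.

    Metrics per epsilon: common-normal distance between the two axis lines
    and the distance between the position points, both in mm.  When the
    eps = 0 normal matrix is rank-deficient, its position is defined only up
    to the null direction (for a hinge: anywhere along the axis); the point
    distance to the minimum-norm representative is then unbounded and is
    reported as +inf, directed along the null direction.
    """
    epsilons = tuple(float(e) for e in epsilons)
    if any(e <= 0 for e in epsilons) or list(epsilons) != sorted(epsilons):
        raise ValueError("epsilons must be positive and ascending")
    S0 = np.asarray(S0, dtype=float).reshape(3)
    base = estimate_asa(ps, AsaConfig(epsilon=0.0, S0=S0))
    rows = []
    for eps in epsilons:
        reg = estimate_asa(ps, AsaConfig(epsilon=eps, S0=S0))
        cn = common_normal_distance(reg.axis, base.axis)
        if base.rank_deficient:
            pd, ddir = np.inf, base.null_direction
        else:
            pd = point_distance(reg.axis, base.axis)
            d = base.axis.S - reg.axis.S
            ddir = d / np.linalg.norm(d) if np.linalg.norm(d) > 1e-15 else None
        rows.append(
            RegularizationRow(
                epsilon=eps,
                common_normal_mm=cn,
                point_distance_mm=float(pd),
                displacement_direction=ddir,
            )
        )
    return RegularizationReport(rows=tuple(rows), baseline=base, S0=S0)


@dataclass(frozen=True)
class SensitivityEntry:
    """SDs (over repetitions) of the noisy-vs-clean comparison metrics."""

    rot_level_deg: float
    trans_level_mm: float
    method: str  # "weighted" (this package) or "soa"
    sd_angle_deg: float
    sd_common_normal_mm: float
    sd_point_distance_mm: float
    repetitions: int


@dataclass(frozen=True)
class SensitivityReport:
    entries: tuple[SensitivityEntry, ...]
    seed: int
    epsilon: float

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "epsilon": self.epsilon,
            "entries": [
                {
                    "rot_level_deg": e.rot_level_deg,
                    "trans_level_mm": e.trans_level_mm,
                    "method": e.method,
                    "sd_angle_deg": e.sd_angle_deg,
                    "sd_common_normal_mm": e.sd_common_normal_mm,
                    "sd_point_distance_mm": e.sd_point_distance_mm,
                    "repetitions": e.repetitions,
                }
                for e in self.entries
            ],
        }


def sensitivity_study(
    ps: PoseSequence,
    noise_levels=DEFAULT_NOISE_LEVELS,
    reps: int = 100,
    epsilon: float = 0.01,
    S0=(0.0, 0.0, 0.0),
    seed: int = 0,
    soa_cfg: SoAConfig | None = None,
) -> SensitivityReport:
    """Noise sensitivity of both estimators on one motion.

    For each (rotation deg, translation mm) noise level and each repetition,
    inject fresh pose noise, re-estimate the axis with both methods, and
    compare each to that method's own noise-free estimate via axis angle,
    common-normal distance and position-point distance.  The standard
    deviation of each metric across repetitions is reported.  Per-repetition
    seeds are spawned deterministically from the master seed, so the report
    is bit-identical across runs with the same seed.
    """
    if reps < 2:
        raise ValueError("need at least 2 repetitions")
    soa_cfg = soa_cfg or SoAConfig()
    S0 = np.asarray(S0, dtype=float).reshape(3)
    clean_tws = twists_from_sequence(ps)
    clean_weighted = estimate_asa(ps, AsaConfig(epsilon=epsilon, S0=S0)).axis
    clean_soa = soa_asa(clean_tws, soa_cfg)
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(reps * len(noise_levels))]
    entries = []
    k = 0
    for rot_deg, trans_mm in noise_levels:
        metrics = {"weighted": [], "soa": []}
        for _ in range(reps):
            noisy = add_pose_noise(ps, NoiseSpec(rot_deg, trans_mm, seed=rep_seeds[k]))
            k += 1
            tws = twists_from_sequence(noisy)
            est_w = estimate_asa(noisy, AsaConfig(epsilon=epsilon, S0=S0)).axis
            est_s = soa_asa(tws, soa_cfg)
            for name, est, ref in (
                ("weighted", est_w, clean_weighted),
                ("soa", est_s, clean_soa),
            ):
                metrics[name].append(
                    (
                        axis_angle(est, ref),
                        common_normal_distance(est, ref),
                        point_distance(est, ref),
                    )
                )
        for name in ("weighted", "soa"):
            arr = np.array(metrics[name])
            sd = arr.std(axis=0, ddof=1)
            entries.append(
                SensitivityEntry(
                    rot_level_deg=float(rot_deg),
                    trans_level_mm=float(trans_mm),
                    method=name,
                    sd_angle_deg=float(sd[0]),
                    sd_common_normal_mm=float(sd[1]),
                    sd_point_distance_mm=float(sd[2]),
                    repetitions=reps,
                )
            )
    return SensitivityReport(entries=tuple(entries), seed=seed, epsilon=epsilon)


def dispersion_study(
    ps: PoseSequence,
    epsilon: float = 0.01,
    S0=(0.0, 0.0, 0.0),
    alpha: float = 0.95,
    soa_cfg: SoAConfig | None = None,
) -> DispersionReport:
    """Full dispersion analysis of one motion.

    Estimates the ASA, then reports the orientation and position confidence
    ellipsoids (from C_omega and C_S), the eigenvalue ratios of each, the
    residual-variance estimate, and the conventional threshold-based RMSE
    dispersion metrics.
    """
    soa_cfg = soa_cfg or SoAConfig()
    cfg = AsaConfig(epsilon=epsilon, S0=np.asarray(S0, dtype=float), alpha=alpha)
    result = estimate_asa(ps, cfg)
    tws = result.twists
    C = result.cov_omega
    orient = confidence_ellipsoid(C.C, alpha=alpha)
    orient_ratios = eigenvalue_ratios(orient.eigenvalues)
    s2 = sigma2_hat(tws, result.axis.S)
    CS = position_covariance(C, s2)
    pos = confidence_ellipsoid(CS.C, alpha=alpha)
    pos_ratios = eigenvalue_ratios(pos.eigenvalues)
    isas = [
        isa_from_twist(tw)
        for tw in tws
        if np.linalg.norm(tw.omega) > soa_cfg.omega_threshold
    ]
    rmse_angle, rmse_dist = rmse_dispersion(isas, result.axis)
    return DispersionReport(
        orientation=orient,
        orientation_ratios=orient_ratios,
        position=pos,
        position_ratios=pos_ratios,
        C_S=CS,
        sigma2_hat=s2,
        rmse_angle_deg=rmse_angle,
        rmse_dist_mm=rmse_dist,
        n_samples=len(tws),
    )
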