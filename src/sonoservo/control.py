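"""Compliant control law and a simulated 7-DoF serial arm.

The arm is a generic redundant 7-joint revolute chain (an iiwa-like layout
with configurable link lengths) carrying the ultrasound probe on its flange.
Forward kinematics and the geometric Jacobian are computed from the chain;
contact with the skin surface feeds back external joint torques through J^T.

The outer loop commands joint velocities with the compliant visual-servoing
law

    q̇_c = D⁻¹ (J(q)^T F_d − τ_ext) + J† V_d

where F_d = (0, 0, f_d, 0, 0, 0)^T is the desired wrench along the probe
z-axis (rotated into the base frame before use), τ_ext the external joint
torques sensed at the joints, D a diagonal damping matrix (d_i = 5 N·m·s by
default) and J† = J^T (J J^T)⁻¹ the Moore–Penrose right pseudoinverse that
maps the desired twist V_d = (ẋ, ẏ, 0, φ̇, θ̇, ψ̇)^T of the scan motion into
joint space.  With this sign convention (τ_ext = J^T times the wrench the
robot exerts on the environment) the force term vanishes exactly when the
contact force matches f_d, so the closed loop regulates the 5 N scan force
while the twist term moves the probe along/towards the vessel.

The inner joint impedance controller (stiffness 500 N·m/rad, damping ratio
0.9 on the real robot) is approximated by a first-order velocity-tracking
lag with time constant 2ζ/ω_n, ω_n = sqrt(k/I_eff); joint dynamics, friction
and hysteresis are not modelled, so the simulated force loop converges to
f_d without the steady-state deficit a real torque-estimation chain shows.

Units: joint angles rad, lengths m inside this module; the phantom world is
in mm and conversions happen at the probe/skin boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .phantom import ContactSurface, contact_wrench
from .transforms import HomogeneousTransform

__all__ = [
    "ArmModel",
    "ArmState",
    "ControlParams",
    "SingularityError",
    "default_arm",
    "forward_kinematics",
    "probe_pose",
    "jacobian",
    "pseudoinverse",
    "compliant_joint_velocities",
    "step_arm",
    "solve_ik",
]

MM_PER_M = 1000.0


class SingularityError(RuntimeError):
    """The arm Jacobian lost row rank; motion must stop."""


@dataclass
class ArmModel:
    """Kinematic chain: per joint a fixed translation then a revolute axis.

    ``joints`` is a sequence of (translation_m (3,), axis unit vector (3,));
    joint i contributes Trans(t_i) · Rot(axis_i, q_i).  ``flange_offset_m``
    closes the chain to the flange frame {f}; ``probe_offset_m`` is the
    CAD-known flange-to-probe translation fT_p.
    """

    joints: Sequence = field(
        default_factory=lambda: [
            ((0.0, 0.0, 0.340), (0.0, 0.0, 1.0)),
            ((0.0, 0.0, 0.0), (0.0, 1.0, 0.0)),
            ((0.0, 0.0, 0.400), (0.0, 0.0, 1.0)),
            ((0.0, 0.0, 0.0), (0.0, 1.0, 0.0)),
            ((0.0, 0.0, 0.400), (0.0, 0.0, 1.0)),
            ((0.0, 0.0, 0.0), (0.0, 1.0, 0.0)),
            ((0.0, 0.0, 0.126), (0.0, 0.0, 1.0)),
        ]
    )
    flange_offset_m: tuple = (0.0, 0.0, 0.060)
    probe_offset_m: tuple = (0.0, 0.0, 0.200)
    joint_limit_rad: float = 2.96

    @property
    def n_joints(self) -> int:
        return len(self.joints)

    @property
    def fTp(self) -> HomogeneousTransform:
        return HomogeneousTransform.from_translation(
            self.probe_offset_m, from_frame="p", to_frame="f"
        )

    @classmethod
    def from_yaml(cls, path) -> "ArmModel":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "joints" in data:
            data["joints"] = [(tuple(t), tuple(a)) for t, a in data["joints"]]
        for key in ("flange_offset_m", "probe_offset_m"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {
            "joints": [[list(t), list(a)] for t, a in self.joints],
            "flange_offset_m": list(self.flange_offset_m),
            "probe_offset_m": list(self.probe_offset_m),
            "joint_limit_rad": self.joint_limit_rad,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


def default_arm() -> ArmModel:
    return ArmModel()


@dataclass
class ArmState:
    """Joint positions, velocities and sensed external torques."""

    q: np.ndarray
    q_dot: np.ndarray
    tau_ext: np.ndarray

    @classmethod
    def at_rest(cls, q) -> "ArmState":
        q = np.asarray(q, dtype=float)
        return cls(q=q, q_dot=np.zeros_like(q), tau_ext=np.zeros_like(q))


@dataclass
class ControlParams:
    """Parameters of the compliant law and the inner-loop approximation."""

    f_d_N: float = 5.0
    damping_Nms: float = 5.0  # diagonal entries d_i of D
    V_d: np.ndarray = field(default_factory=lambda: np.zeros(6))
    inner_stiffness_Nm_per_rad: float = 500.0
    inner_damping_ratio: float = 0.9
    effective_inertia_kgm2: float = 1.0
    dt_s: float = 0.005
    singularity_cond_threshold: float = 1e8

    def __post_init__(self) -> None:
        self.V_d = np.asarray(self.V_d, dtype=float)
        if self.damping_Nms <= 0:
            raise ValueError("damping must be positive definite")
        if self.dt_s <= 0:
            raise ValueError("timestep must be positive")

    @property
    def velocity_lag_s(self) -> float:
        """First-order lag constant standing in for the joint impedance loop."""
        omega_n = np.sqrt(self.inner_stiffness_Nm_per_rad / self.effective_inertia_kgm2)
        return 2.0 * self.inner_damping_ratio / omega_n


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------
def _axis_angle_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis (hot path: no scipy objects)."""
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def _joint_frames(q: np.ndarray, model: ArmModel):
    """Origins and axes of every joint plus the flange transform, base frame."""
    q = np.asarray(q, dtype=float)
    if q.shape != (model.n_joints,):
        raise ValueError(f"expected {model.n_joints} joint values, got {q.shape}")
    R = np.eye(3)
    p = np.zeros(3)
    origins, axes = [], []
    for (trans, axis), angle in zip(model.joints, q):
        p = p + R @ np.asarray(trans, dtype=float)
        a_base = R @ np.asarray(axis, dtype=float)
        origins.append(p)
        axes.append(a_base)
        R = R @ _axis_angle_matrix(np.asarray(axis, dtype=float), angle)
    p = p + R @ np.asarray(model.flange_offset_m, dtype=float)
    T = np.eye(4)
    T[:3, :3] = R
    T[:3, 3] = p
    return T, origins, axes


def forward_kinematics(q, model: ArmModel) -> HomogeneousTransform:
    """Base-from-flange transform bT_f for joint configuration q."""
    q = np.asarray(q, dtype=float)
    if np.any(np.abs(q) > model.joint_limit_rad):
        warnings.warn("joint configuration exceeds joint limits", stacklevel=2)
    T, _, _ = _joint_frames(q, model)
    return HomogeneousTransform(T, from_frame="f", to_frame="b")


def probe_pose(q, model: ArmModel) -> HomogeneousTransform:
    """Base-from-probe transform bT_p = bT_f · fT_p (translation in metres)."""
    return forward_kinematics(q, model) @ model.fTp


def jacobian(q, model: ArmModel, point_m: Optional[np.ndarray] = None) -> np.ndarray:
    """Geometric Jacobian (6 x n) at the flange origin or a given base point.

    Rows 0-2 map joint rates to linear velocity of the reference point, rows
    3-5 to angular velocity, both in the base frame.
    """
    T, origins, axes = _joint_frames(np.asarray(q, dtype=float), model)
    p = T[:3, 3] if point_m is None else np.asarray(point_m, dtype=float)
    J = np.zeros((6, model.n_joints))
    for i, (o, a) in enumerate(zip(origins, axes)):
        J[:3, i] = np.cross(a, p - o)
        J[3:, i] = a
    return J


def probe_frame(q, model: ArmModel):
    """Probe pose (m) and the 6 x n geometric Jacobian at the probe tip.

    One chain evaluation for both quantities; the hot path of the closed
    loop.
    """
    T, origins, axes = _joint_frames(np.asarray(q, dtype=float), model)
    p = T[:3, 3] + T[:3, :3] @ np.asarray(model.probe_offset_m, dtype=float)
    J = np.zeros((6, model.n_joints))
    for i, (o, a) in enumerate(zip(origins, axes)):
        J[:3, i] = np.cross(a, p - o)
        J[3:, i] = a
    pose = HomogeneousTransform.from_rotation_translation(T[:3, :3], p, "p", "b")
    return pose, J


def pseudoinverse(J: np.ndarray, cond_threshold: float = 1e8) -> np.ndarray:
    """Moore–Penrose right pseudoinverse J† = J^T (J J^T)⁻¹.

    Raises :class:`SingularityError` when J J^T is ill-conditioned; the
    caller must stop motion rather than command a near-singular velocity.
    """
    J = np.asarray(J, dtype=float)
    JJt = J @ J.T
    cond = np.linalg.cond(JJt)
    if not np.isfinite(cond) or cond > cond_threshold:
        raise SingularityError(f"Jacobian near row-rank deficiency (cond(JJ^T) = {cond:.3g})")
    return J.T @ np.linalg.inv(JJt)


# ---------------------------------------------------------------------------
# compliant law
# ---------------------------------------------------------------------------
def desired_wrench(f_d_N: float, probe_rotation_b: np.ndarray) -> np.ndarray:
    """F_d = (0, 0, f_d)^T along the probe z-axis, expressed in base frame."""
    F = np.zeros(6)
    F[:3] = np.asarray(probe_rotation_b, dtype=float)[:, 2] * f_d_N
    return F


def compliant_joint_velocities(
    state: ArmState,
    params: ControlParams,
    J: np.ndarray,
    probe_rotation_b: np.ndarray | None = None,
    F_d: np.ndarray | None = None,
    V_d: np.ndarray | None = None,
) -> np.ndarray:
    """Evaluate the compliant velocity law q̇_c = D⁻¹(J^T F_d − τ_ext) + J† V_d.

    ``F_d`` may be passed directly (6-vector, base frame); otherwise it is
    built from ``params.f_d_N`` along the probe z-axis given
    ``probe_rotation_b``.  ``V_d`` defaults to ``params.V_d`` (base frame).
    Works for any chain length (D is d_i · I of matching size).
    """
    J = np.asarray(J, dtype=float)
    n = J.shape[1]
    if F_d is None:
        if probe_rotation_b is None:
            raise ValueError("either F_d or probe_rotation_b is required")
        F_d = desired_wrench(params.f_d_N, probe_rotation_b)
    F_d = np.asarray(F_d, dtype=float)
    V_d = params.V_d if V_d is None else np.asarray(V_d, dtype=float)
    tau_ext = np.asarray(state.tau_ext, dtype=float)
    force_term = (J.T @ F_d - tau_ext) / params.damping_Nms
    twist_term = pseudoinverse(J, params.singularity_cond_threshold) @ V_d if np.any(V_d) else np.zeros(n)
    return force_term + twist_term


# ---------------------------------------------------------------------------
# simulation step
# ---------------------------------------------------------------------------
def step_arm(
    state: ArmState,
    qdot_c: np.ndarray,
    model: ArmModel,
    surface: Optional[ContactSurface],
    dt: float,
    params: ControlParams = ControlParams(),
    max_substep_s: float = 0.005,
) -> ArmState:
    """Advance the simulated arm by ``dt`` under commanded joint velocities.

    Joint velocities track the command through the first-order inner-loop
    lag; positions integrate the velocities; after each substep the contact
    wrench at the probe tip is mapped into external joint torques through
    the tip Jacobian.  Returns a new :class:`ArmState`.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    qdot_c = np.asarray(qdot_c, dtype=float)
    q = np.asarray(state.q, dtype=float).copy()
    q_dot = np.asarray(state.q_dot, dtype=float).copy()
    tau_ext = np.asarray(state.tau_ext, dtype=float).copy()
    lag = params.velocity_lag_s
    n_sub = max(1, int(np.ceil(dt / max_substep_s)))
    h = dt / n_sub
    for _ in range(n_sub):
        alpha = min(1.0, h / max(lag, 1e-9))
        q_dot = q_dot + alpha * (qdot_c - q_dot)
        q = q + q_dot * h
        if surface is not None:
            pose_m, J_tip = probe_frame(q, model)
            tip_vel_mm = (J_tip[:3] @ q_dot) * MM_PER_M
            pose_mm = HomogeneousTransform.from_rotation_translation(
                pose_m.rotation, pose_m.translation * MM_PER_M, "p", "b"
            )
            wrench = contact_wrench(pose_mm, tip_vel_mm, surface)
            tau_ext = J_tip[:3].T @ wrench[:3]
        else:
            tau_ext = np.zeros_like(q)
    return ArmState(q=q, q_dot=q_dot, tau_ext=tau_ext)


# ---------------------------------------------------------------------------
# inverse kinematics (for placing the arm at the scan start)
# ---------------------------------------------------------------------------
def _planar_guess(target_pose: HomogeneousTransform, model: ArmModel) -> np.ndarray:
    """Elbow-down planar 2-link guess for a downward-pointing probe target.

    Treats joints 2 and 4 as a planar 2-link chain in the vertical plane of
    the target and joint 6 as the wrist closing the orientation to straight
    down; the base joint yaws the plane toward the target.  Only a warm
    start for the numeric solve — exactness is not required.
    """
    p = target_pose.translation
    lengths = [np.linalg.norm(j[0]) for j in model.joints]
    z_shoulder = lengths[0]
    L1 = lengths[2] if model.n_joints > 2 else 0.4
    L2 = lengths[4] if model.n_joints > 4 else 0.4
    wrist = (
        (lengths[6] if model.n_joints > 6 else 0.0)
        + np.linalg.norm(model.flange_offset_m)
        + np.linalg.norm(model.probe_offset_m)
    )
    yaw = np.arctan2(p[1], p[0])
    radial = np.hypot(p[0], p[1])
    # wrist center with the last link pointing straight down
    wx, wz = radial, p[2] + wrist - z_shoulder
    d = np.hypot(wx, wz)
    d = min(d, L1 + L2 - 1e-6)
    cos_elbow = np.clip((L1**2 + L2**2 - d**2) / (2 * L1 * L2), -1.0, 1.0)
    elbow = np.arccos(cos_elbow)
    q4 = -(np.pi - elbow)  # elbow folded towards the base
    alpha = np.arctan2(wx, wz)  # from vertical
    beta = np.arcsin(np.clip(L2 * np.sin(elbow) / max(d, 1e-9), -1.0, 1.0))
    q2 = alpha + beta
    q6 = np.pi - q2 - q4  # flange z down
    q6 = np.mod(q6 + np.pi, 2 * np.pi) - np.pi
    guess = np.zeros(model.n_joints)
    if model.n_joints >= 6:
        guess[0], guess[1], guess[3], guess[5] = yaw, q2, q4, q6
    return guess


def solve_ik(
    target_pose: HomogeneousTransform,
    model: ArmModel,
    q0: Optional[np.ndarray] = None,
    max_iters: int = 300,
    tol: float = 1e-9,
) -> np.ndarray:
    """Damped least-squares IK for the probe pose (translation in metres).

    Deterministic: a fixed elbow-bent initial guess is used unless ``q0`` is
    given.  Raises if the pose error does not converge below ``tol``.
    """
    if q0 is None:
        q = _planar_guess(target_pose, model)
    else:
        q = np.asarray(q0, dtype=float).copy()
    target_p = target_pose.translation
    target_R = target_pose.rotation
    fTp = model.fTp.matrix
    lam = 1e-3
    for _ in range(max_iters):
        T, _, _ = _joint_frames(q, model)
        T = T @ fTp
        err_p = target_p - T[:3, 3]
        R_err = target_R @ T[:3, :3].T
        err_w = Rotation.from_matrix(R_err).as_rotvec()
        err = np.concatenate([err_p, err_w])
        if np.dot(err, err) < tol:
            return q
        J = jacobian(q, model, point_m=T[:3, 3])
        JJt = J @ J.T + lam * np.eye(6)
        step = J.T @ np.linalg.solve(JJt, err)
        step_norm = np.linalg.norm(step)
        if step_norm > 0.5:  # trust region keeps the chain near the guess
            step *= 0.5 / step_norm
        q = np.mod(q + step + np.pi, 2 * np.pi) - np.pi  # revolute: 2*pi-periodic
    raise RuntimeError(f"IK did not converge (residual {np.linalg.norm(err):.3g} m/rad)")
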