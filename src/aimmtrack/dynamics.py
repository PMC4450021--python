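"""Mode-conditioned motion models for the augmented cell state.

The tracked state of one cell is the 6-vector

    X = [x, y, vx, vy, omega, s]

with position in pixels, velocity in pixels per frame interval, turn rate
``omega`` in radians per frame interval, and blob area ``s`` in px^2.  Three
motion modes are supported:

* **ACV** — augmented (nearly) constant velocity: independent motion, area
  held constant.
* **ACT1** — augmented coordinate turn for collision: velocity rotates at the
  cell's own turn rate and the area is scaled by the collision control
  ``lambda`` in [1, 2] (a merged blob grows toward the sum of the colliders).
* **ACT2** — augmented coordinate turn for division/splitting: same
  kinematics, area scaled by the division control ``kappa`` in [0, 1].

Process noise enters through a diagonal gain G = diag(T^2/2, T^2/2, T, T,
1, 1) applied to a 6-vector draw v ~ N(0, Q) with Q diagonal.  Measurements
observe (x, y, s) only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple

import numpy as np

MODES = ("acv", "act1", "act2")
STATE_DIM = 6
#: threshold below which |omega*T| is treated as a straight-line limit
OMEGA_EPS = 1e-6

# measurement matrix: rows select x, y and s
H = np.zeros((3, STATE_DIM))
H[0, 0] = 1.0
H[1, 1] = 1.0
H[2, 5] = 1.0


class CellState(NamedTuple):
    """Augmented state of one cell (positions px, velocities px/frame)."""

    x: float
    y: float
    vx: float
    vy: float
    omega: float  # rad per frame interval
    s: float      # area, px^2

    def to_array(self) -> np.ndarray:
        return np.asarray(self, dtype=float)

    @classmethod
    def from_array(cls, a: np.ndarray) -> "CellState":
        return cls(*(float(v) for v in np.asarray(a).ravel()[:STATE_DIM]))


@dataclass(frozen=True)
class TurnRateNoise:
    """Variance of the per-frame Gaussian turn-rate increment."""

    delta_cov: float = 0.01  # rad^2

    def __post_init__(self) -> None:
        if self.delta_cov < 0:
            raise ValueError("turn-rate increment variance must be >= 0")


@dataclass(frozen=True)
class ModeModel:
    """One motion mode: id, diagonal process noise and sampling interval."""

    mode: Literal["acv", "act1", "act2"]
    Q: np.ndarray = field(default_factory=lambda: np.zeros(STATE_DIM))
    T: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        q = np.asarray(self.Q, dtype=float)
        if q.shape != (STATE_DIM,) or np.any(q < 0):
            raise ValueError("Q must be 6 nonnegative diagonal entries")
        object.__setattr__(self, "Q", q)
        if self.T <= 0:
            raise ValueError("sampling interval T must be positive")


def noise_gain(T: float) -> np.ndarray:
    """Diagonal noise gain G: acceleration-like on position, direct on
    velocity, unit on turn rate and area."""
    return np.diag([T * T / 2.0, T * T / 2.0, T, T, 1.0, 1.0])


def acv_transition(T: float) -> tuple[np.ndarray, np.ndarray]:
    """Constant-velocity transition matrix and noise gain.

    Returns ``(F, G)`` with F the 6x6 kinematic matrix (identity plus the
    T-couplings position<-velocity; turn rate and area persist unchanged).
    """
    if T <= 0:
        raise ValueError("T must be positive")
    F = np.eye(STATE_DIM)
    F[0, 2] = T
    F[1, 3] = T
    return F, noise_gain(T)


def _ct_coeffs(omega: np.ndarray, T: float):
    """sin/cos coordinate-turn coefficients with the omega -> 0 limit.

    Returns (a, b, c, d) with a = sin(wT)/w, b = (1-cos(wT))/w,
    c = cos(wT), d = sin(wT).
    """
    w = np.asarray(omega, dtype=float)
    small = np.abs(w * T) < OMEGA_EPS
    wsafe = np.where(small, 1.0, w)
    a = np.where(small, T, np.sin(wsafe * T) / wsafe)
    b = np.where(small, 0.0, (1.0 - np.cos(wsafe * T)) / wsafe)
    c = np.where(small, 1.0, np.cos(wsafe * T))
    d = np.where(small, 0.0, np.sin(wsafe * T))
    return a, b, c, d


def ct_jacobian_column(vx: float, vy: float, omega: float, T: float) -> np.ndarray:
    """Derivative of the coordinate-turn position/velocity map w.r.t. omega.

    Entries [f11, f21, f31, f41]: sensitivities of (x', y', vx', vy') to the
    turn rate, evaluated at the given velocity.  The omega -> 0 limits follow
    from the series expansions (f11 -> -vy T^2/2, f21 -> vx T^2/2,
    f31 -> -vy T, f41 -> vx T).
    """
    if abs(omega * T) < OMEGA_EPS:
        return np.array(
            [-vy * T * T / 2.0, vx * T * T / 2.0, -vy * T, vx * T]
        )
    wT = omega * T
    sw, cw = np.sin(wT), np.cos(wT)
    w2 = omega * omega
    da = (wT * cw - sw) / w2          # d/dw [sin(wT)/w]
    db = (wT * sw + cw - 1.0) / w2    # d/dw [(1-cos(wT))/w]
    f11 = vx * da - vy * db
    f21 = vx * db + vy * da
    f31 = -T * (vx * sw + vy * cw)
    f41 = T * (vx * cw - vy * sw)
    return np.array([f11, f21, f31, f41])


def ct_transition(
    omega: float,
    T: float,
    control: float,
    kind: Literal["collision", "division"] = "collision",
    velocity: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Coordinate-turn transition matrix for the collision/division modes.

    The upper-left 4x4 block is the standard coordinate-turn matrix in
    ``omega``; the 5th column carries the turn-rate Jacobian evaluated at
    ``velocity`` (EKF-style linearization about the prior state); the area
    diagonal holds the control variable (``lambda`` in [1, 2] for collision,
    ``kappa`` in [0, 1] for division).
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if kind == "collision":
        if not 1.0 <= control <= 2.0:
            raise ValueError("collision control lambda must lie in [1, 2]")
    elif kind == "division":
        if not 0.0 <= control <= 1.0:
            raise ValueError("division control kappa must lie in [0, 1]")
    else:
        raise ValueError(f"unknown kind {kind!r}")
    a, b, c, d = (float(v) for v in _ct_coeffs(np.asarray(omega), T))
    F = np.eye(STATE_DIM)
    F[0, 2], F[0, 3] = a, -b
    F[1, 2], F[1, 3] = b, a
    F[2, 2], F[2, 3] = c, -d
    F[3, 2], F[3, 3] = d, c
    F[:4, 4] = ct_jacobian_column(velocity[0], velocity[1], omega, T)
    F[5, 5] = control
    return F


def ct_apply(states: np.ndarray, T: float, control: float) -> np.ndarray:
    """Exact coordinate-turn propagation of an (N, 6) particle block.

    Each row's kinematics are rotated with its *own* turn-rate component
    (full nonlinear map, no linearization); the turn rate persists and the
    area is scaled by ``control``.
    """
    X = np.atleast_2d(np.asarray(states, dtype=float))
    a, b, c, d = _ct_coeffs(X[:, 4], T)
    out = np.empty_like(X)
    out[:, 0] = X[:, 0] + a * X[:, 2] - b * X[:, 3]
    out[:, 1] = X[:, 1] + b * X[:, 2] + a * X[:, 3]
    out[:, 2] = c * X[:, 2] - d * X[:, 3]
    out[:, 3] = d * X[:, 2] + c * X[:, 3]
    out[:, 4] = X[:, 4]
    out[:, 5] = control * X[:, 5]
    return out


def acv_apply(states: np.ndarray, T: float) -> np.ndarray:
    """Constant-velocity propagation of an (N, 6) particle block."""
    X = np.atleast_2d(np.asarray(states, dtype=float))
    out = X.copy()
    out[:, 0] += T * X[:, 2]
    out[:, 1] += T * X[:, 3]
    return out


def evolve_turn_rate(
    omega_prev: float, noise: TurnRateNoise, rng: np.random.Generator
) -> float:
    """Random-walk step of the turn rate: omega_k = omega_{k-1} + delta."""
    if noise.delta_cov == 0:
        return float(omega_prev)
    return float(omega_prev + rng.normal(0.0, np.sqrt(noise.delta_cov)))


def process_noise(
    mode: ModeModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n samples of G @ v with v ~ N(0, diag(Q))."""
    gains = np.array(
        [mode.T**2 / 2.0, mode.T**2 / 2.0, mode.T, mode.T, 1.0, 1.0]
    )
    std = gains * np.sqrt(mode.Q)
    return rng.standard_normal((n, STATE_DIM)) * std


def propagate(
    state: CellState,
    mode: ModeModel,
    control: float = 1.0,
    rng: np.random.Generator | None = None,
) -> CellState:
    """One-step state propagation under one motion mode.

    ACV ignores ``control``; the ACT modes rotate the velocity with the
    state's own turn rate and scale the area by ``control``.  If ``rng`` is
    given, process noise G v with v ~ N(0, Q) is added.
    """
    X = state.to_array()[None, :]
    if mode.mode == "acv":
        out = acv_apply(X, mode.T)
    else:
        if mode.mode == "act1" and not 1.0 <= control <= 2.0:
            raise ValueError("lambda out of [1, 2]")
        if mode.mode == "act2" and not 0.0 <= control <= 1.0:
            raise ValueError("kappa out of [0, 1]")
        out = ct_apply(X, mode.T, control)
    if rng is not None and np.any(mode.Q > 0):
        out = out + process_noise(mode, 1, rng)
    return CellState.from_array(out[0])


def measure(
    state: CellState,
    R: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Noisy observation z = (x, y, s) + w, w ~ N(0, diag(R))."""
    r = np.asarray(R, dtype=float)
    if r.ndim == 2:
        r = np.diag(r)
    z = H @ state.to_array()
    if rng is not None and np.any(r > 0):
        z = z + rng.standard_normal(3) * np.sqrt(r)
    return z
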