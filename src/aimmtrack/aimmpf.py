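"""Augmented interacting-multiple-model particle filter (AIMMPF).

One filter instance tracks one cell.  Three mode-conditioned particle
clouds (ACV, ACT1, ACT2) evolve under a stationary Markov chain over the
modes.  Each frame runs

    mix -> predict(lambda, kappa) -> update -> mode-probability update
        -> resample -> estimate

Two feedback loops distinguish the filter from a plain IMM particle
filter: the event-probability feedback supplies the area-scaling controls
``lambda`` (collision) and ``kappa`` (division) to the ACT transition
matrices, and the turn-rate feedback stores the posterior per-mode turn
rate estimates for the next frame's coordinate-turn propagation.

Likelihoods are computed in log space so that mode competition survives
severely mismatched predictions (e.g. a suddenly doubled area at a merge).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .dynamics import (
    MODES,
    STATE_DIM,
    CellState,
    acv_apply,
    ct_apply,
)

_LOG2PI = float(np.log(2.0 * np.pi))


def scenario1_q() -> dict[str, np.ndarray]:
    """Default per-mode diagonal process noise (collision-rich profile)."""
    return {
        "acv": np.array([30.0, 30.0, 0.1, 0.1, 0.01, 0.01]),
        "act1": np.array([40.0, 40.0, 0.1, 0.1, 0.01, 0.01]),
        "act2": np.array([40.0, 40.0, 0.1, 0.1, 0.01, 0.01]),
    }


@dataclass(frozen=True)
class FilterConfig:
    """AIMMPF tuning parameters.

    ``trans`` rows give the Markov mode-transition probabilities from
    (ACV, ACT1, ACT2); ``Q`` maps mode id to the 6 diagonal process-noise
    variances; ``R`` holds the measurement noise variances on (x, y, s).
    Initial particle spreads set how confidently a track is born from a
    single detection.
    """

    n_particles: int = 500
    T: float = 1.0
    trans: np.ndarray = field(
        default_factory=lambda: np.array(
            [[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]]
        )
    )
    init_mode_probs: np.ndarray = field(
        default_factory=lambda: np.array([0.8, 0.1, 0.1])
    )
    Q: dict = field(default_factory=scenario1_q)
    R: np.ndarray = field(default_factory=lambda: np.array([1.0, 1.0, 1.0]))
    omega0: float = 0.8  # rad per frame interval
    # variance of the per-frame turn-rate increment about the fed-back
    # estimate: each ACT particle's omega is redrawn as omega_hat + delta
    turn_rate_delta: float = 0.01
    init_pos_std: float = 1.0
    init_vel_std: float = 2.0
    init_omega_std: float = 0.4
    init_area_std: float = 2.0
    # post-resampling roughening: jitter each resampled particle by this
    # fraction of the predicted cloud's per-dimension spread, preserving
    # diversity in the unobserved components (velocity, turn rate) when
    # the effective sample size collapses
    roughening: float = 0.2

    def __post_init__(self) -> None:
        t = np.asarray(self.trans, dtype=float)
        if t.shape != (3, 3) or np.any(t < 0) or not np.allclose(t.sum(axis=1), 1.0):
            raise ValueError("trans must be a 3x3 row-stochastic matrix")
        object.__setattr__(self, "trans", t)
        m = np.asarray(self.init_mode_probs, dtype=float)
        if m.shape != (3,) or np.any(m < 0) or not np.isclose(m.sum(), 1.0):
            raise ValueError("init_mode_probs must be a probability 3-vector")
        object.__setattr__(self, "init_mode_probs", m)
        r = np.asarray(self.R, dtype=float)
        if r.ndim == 2:
            r = np.diag(r)
        if r.shape != (3,) or np.any(r <= 0):
            raise ValueError("R must hold 3 positive variances")
        object.__setattr__(self, "R", r)
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")


@dataclass
class ModeBank:
    """Per-cell filter state: three particle clouds plus mode probabilities.

    ``particles`` has shape (3, N, 6) in mode order (ACV, ACT1, ACT2) and
    ``weights`` (3, N) are normalized within each mode.  ``omega_hat``
    carries the posterior turn-rate estimates of the two coordinate-turn
    modes (the red feedback loop).
    """

    particles: np.ndarray
    weights: np.ndarray
    mode_probs: np.ndarray
    trans: np.ndarray
    omega_hat: np.ndarray  # (2,): ACT1, ACT2
    diverged: bool = False

    def copy(self) -> "ModeBank":
        return ModeBank(
            self.particles.copy(),
            self.weights.copy(),
            self.mode_probs.copy(),
            self.trans.copy(),
            self.omega_hat.copy(),
            self.diverged,
        )


class TrackEstimate(NamedTuple):
    """Combined (mode-probability-weighted) state estimate for one frame."""

    state: CellState
    mode_probs: np.ndarray
    frame: int = -1


def make_bank(
    x: float,
    y: float,
    s: float,
    config: FilterConfig,
    rng: np.random.Generator,
    vx: float = 0.0,
    vy: float = 0.0,
) -> ModeBank:
    """Initialize a filter from one detection (position and area); velocity
    defaults to zero and the turn rate to ``omega0``."""
    n = config.n_particles
    cloud = np.empty((n, STATE_DIM))
    cloud[:, 0] = x + rng.normal(0.0, config.init_pos_std, n)
    cloud[:, 1] = y + rng.normal(0.0, config.init_pos_std, n)
    cloud[:, 2] = vx + rng.normal(0.0, config.init_vel_std, n)
    cloud[:, 3] = vy + rng.normal(0.0, config.init_vel_std, n)
    cloud[:, 4] = config.omega0 + rng.normal(0.0, config.init_omega_std, n)
    cloud[:, 5] = np.maximum(1.0, s + rng.normal(0.0, config.init_area_std, n))
    particles = np.stack([cloud, cloud.copy(), cloud.copy()])
    weights = np.full((3, n), 1.0 / n)
    return ModeBank(
        particles=particles,
        weights=weights,
        mode_probs=config.init_mode_probs.copy(),
        trans=config.trans.copy(),
        omega_hat=np.array([config.omega0, config.omega0]),
    )


def systematic_resample(
    weights: np.ndarray, rng: np.random.Generator, n: int | None = None
) -> np.ndarray:
    """Systematic resampling: indices with expected copy count n*w_i and
    per-particle deviation below one copy."""
    w = np.asarray(weights, dtype=float)
    n_out = len(w) if n is None else n
    positions = (np.arange(n_out) + rng.uniform()) / n_out
    cum = np.cumsum(w)
    cum[-1] = 1.0  # guard rounding
    return np.searchsorted(cum, positions)


def resample(
    particles: np.ndarray, weights: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Resample one cloud to equal weights."""
    idx = systematic_resample(weights, rng)
    n = len(idx)
    return particles[idx], np.full(n, 1.0 / n)


def mix(
    bank: ModeBank,
    rng: np.random.Generator,
    turn_rate_delta: float = 0.0,
) -> tuple[ModeBank, np.ndarray]:
    """IMM mixing by mixture resampling.

    Predicted mode probabilities c_bar_j = sum_i P_ij M_i; each mode's new
    cloud is drawn from the union of clouds with per-source weights
    P_ij M_i / c_bar_j.  A particle entering a coordinate-turn mode from
    the constant-velocity mode carries no meaningful turn rate, so its
    omega component is re-seeded from the destination mode's fed-back
    posterior estimate (omega_hat plus an increment of variance
    ``turn_rate_delta``).  Returns the mixed bank and c_bar.
    """
    c_bar = bank.trans.T @ bank.mode_probs
    if np.all(c_bar <= 0):
        raise FloatingPointError("degenerate transition matrix: all c_bar zero")
    n = bank.particles.shape[1]
    pooled = bank.particles.reshape(3 * n, STATE_DIM)
    new_particles = np.empty_like(bank.particles)
    delta_std = np.sqrt(turn_rate_delta)
    for j in range(3):
        if c_bar[j] <= 0:
            # unreachable mode this frame: carry the cloud along untouched
            new_particles[j] = bank.particles[j]
            continue
        mix_w = bank.trans[:, j] * bank.mode_probs / c_bar[j]  # over sources
        pooled_w = (mix_w[:, None] * bank.weights).ravel()
        pooled_w = pooled_w / pooled_w.sum()
        idx = systematic_resample(pooled_w, rng, n)
        cloud = pooled[idx].copy()
        if j > 0:
            from_acv = idx < n
            k = int(from_acv.sum())
            if k:
                cloud[from_acv, 4] = bank.omega_hat[j - 1] + rng.normal(
                    0.0, delta_std, k
                )
        new_particles[j] = cloud
    out = bank.copy()
    out.particles = new_particles
    out.weights = np.full((3, n), 1.0 / n)
    return out, c_bar


def predict(
    bank: ModeBank,
    lam: float,
    kappa: float,
    config: FilterConfig,
    rng: np.random.Generator,
) -> ModeBank:
    """Mode-conditioned propagation with event-control feedback.

    ACV moves at constant velocity.  For ACT1/ACT2 each particle's
    velocity is rotated with the particle's own (persistent) turn rate —
    so selection integrates turn-rate evidence across frames — and the
    area is scaled by ``lam`` (in [1, 2]) / ``kappa`` (in [0, 1]).  The
    turn-rate random walk is realized by the sigma_omega entry of Q.
    """
    if not 1.0 <= lam <= 2.0:
        raise ValueError("lambda out of [1, 2]")
    if not 0.0 <= kappa <= 1.0:
        raise ValueError("kappa out of [0, 1]")
    out = bank.copy()
    T = config.T
    n = bank.particles.shape[1]
    gains = np.array([T * T / 2.0, T * T / 2.0, T, T, 1.0, 1.0])
    for j, mode in enumerate(MODES):
        if mode == "acv":
            prop = acv_apply(bank.particles[j], T)
        else:
            prop = ct_apply(bank.particles[j], T, lam if mode == "act1" else kappa)
        std = gains * np.sqrt(np.asarray(config.Q[mode], dtype=float))
        prop = prop + rng.standard_normal((n, STATE_DIM)) * std
        prop[:, 5] = np.maximum(prop[:, 5], 1.0)  # areas stay physical
        out.particles[j] = prop
    return out


def update(
    bank: ModeBank, z: np.ndarray, R: np.ndarray
) -> tuple[ModeBank, np.ndarray]:
    """Weight particles by the Gaussian likelihood of z = (x, y, s).

    Returns the reweighted bank and the per-mode log-likelihoods
    log Lambda_j = log of the weighted mean unnormalized weight.  Computed
    in log space; if a mode underflows entirely its weights are floored to
    uniform and the bank is flagged diverged.
    """
    z = np.asarray(z, dtype=float)
    r = np.asarray(R, dtype=float)
    if r.ndim == 2:
        r = np.diag(r)
    out = bank.copy()
    loglik = np.empty(3)
    const = -0.5 * (3 * _LOG2PI + np.log(r).sum())
    for j in range(3):
        pred = bank.particles[j][:, [0, 1, 5]]
        ll = const - 0.5 * ((pred - z) ** 2 / r).sum(axis=1)
        prior = np.log(np.maximum(bank.weights[j], 1e-300))
        logw = prior + ll
        m = logw.max()
        if not np.isfinite(m):
            out.weights[j] = 1.0 / len(logw)
            loglik[j] = -np.inf
            out.diverged = True
            continue
        w = np.exp(logw - m)
        loglik[j] = m + np.log(w.sum())  # log of weighted mean likelihood
        out.weights[j] = w / w.sum()
    return out, loglik


def update_mode_probs(
    c_bar: np.ndarray, loglik: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Posterior mode probabilities M_j proportional to c_bar_j Lambda_j.

    Returns (probabilities, degenerate); when every mode's likelihood
    vanishes the prior c_bar is kept and degenerate=True.
    """
    c = np.asarray(c_bar, dtype=float)
    ll = np.asarray(loglik, dtype=float)
    finite = np.isfinite(ll) & (c > 0)
    if not np.any(finite):
        return c / c.sum(), True
    shift = ll[finite].max()
    num = np.where(finite, c * np.exp(np.clip(ll - shift, -700, 0)), 0.0)
    tot = num.sum()
    if tot <= 0:
        return c / c.sum(), True
    return num / tot, False


def estimate(bank: ModeBank, frame: int = -1) -> tuple[ModeBank, TrackEstimate]:
    """Combined estimate and turn-rate feedback.

    The output state is the mode-probability-weighted mixture of the
    per-mode weighted particle means; the posterior ACT1/ACT2 turn-rate
    means are written back into the bank for the next frame.
    """
    means = np.einsum("jn,jnd->jd", bank.weights, bank.particles)
    combined = bank.mode_probs @ means
    out = bank.copy()
    out.omega_hat = np.array([means[1, 4], means[2, 4]])
    return out, TrackEstimate(
        CellState.from_array(combined), bank.mode_probs.copy(), frame
    )


def step(
    bank: ModeBank,
    z: np.ndarray | None,
    config: FilterConfig,
    rng: np.random.Generator,
    lam: float = 1.0,
    kappa: float = 0.0,
    frame: int = -1,
) -> tuple[ModeBank, TrackEstimate]:
    """One full AIMMPF cycle for one cell.

    With a measurement: mix, predict with the event controls, weight,
    update the mode probabilities, resample and form the combined
    estimate.  Without one (missed detection) the update is skipped and
    the predicted mode probabilities c_bar are kept.
    """
    mixed, c_bar = mix(bank, rng, config.turn_rate_delta)
    pred = predict(mixed, lam, kappa, config, rng)
    if z is None:
        pred.mode_probs = c_bar / c_bar.sum()
        return estimate(pred, frame)
    upd, loglik = update(pred, z, config.R)
    probs, degenerate = update_mode_probs(c_bar, loglik)
    upd.mode_probs = probs
    upd.diverged = upd.diverged or degenerate
    n = upd.particles.shape[1]
    for j in range(3):
        spread = upd.particles[j].std(axis=0)  # pre-resample diversity
        upd.particles[j], upd.weights[j] = resample(
            upd.particles[j], upd.weights[j], rng
        )
        if config.roughening > 0:
            jitter = config.roughening * spread
            upd.particles[j] = upd.particles[j] + rng.standard_normal(
                (n, STATE_DIM)
            ) * jitter
            upd.particles[j][:, 5] = np.maximum(upd.particles[j][:, 5], 1.0)
    return estimate(upd, frame)


def acv_only_config(config: FilterConfig) -> FilterConfig:
    """Restrict a configuration to the constant-velocity mode (identity
    transitions, all probability on ACV) — a plain bootstrap filter."""
    return replace(
        config,
        trans=np.eye(3),
        init_mode_probs=np.array([1.0, 0.0, 0.0]),
    )
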