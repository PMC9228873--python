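"""Non-stationary multi-armed bandit agents over latent-distance rewards.

Six arms (one per motion class) pay a time-varying reward: the latent
distance between the player's current attempt at that motion and the motion's
target centroid.  An agent keeps a per-arm estimate of the expected reward,
turns it into a softmax selection probability, pulls one arm per iteration,
and updates only that arm's knowledge (plus, for the Kalman family, every
other arm's uncertainty).

Five agents are provided:

- ``boltzmann`` — constant-learning-rate tracker, softmax on the estimates;
- ``boltzmann_ucb`` — the same tracker with the classic optimism bonus
  c*sqrt(ln t / (2 N_k)) added before the softmax;
- ``kalman`` — per-arm ("sibling") Kalman filter whose gain acts as an
  adaptive learning rate, while untested arms' variance inflates by the
  innovation variance every step;
- ``kalman_iucb`` — Kalman tracker with an uncertainty bonus
  c*sqrt(posterior variance + observation variance);
- ``kalman_ts`` — Kalman tracker scored by Thompson draws from each arm's
  posterior.

Evaluation uses the cumulative weighted-probability error
ae(T) = sum_{t<=T} sum_k |P*_k(t) mu*_k(t) - P_k(t) mu^_k(t)|, where the
starred quantities come from the full true reward vector passed through a
softmax at reference temperature tau* = 2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

AGENT_KINDS = ("boltzmann", "boltzmann_ucb", "kalman", "kalman_iucb", "kalman_ts")
KALMAN_KINDS = ("kalman", "kalman_iucb", "kalman_ts")

#: Hyperparameter grids searched per agent kind.
TABLE4_GRIDS: dict[str, dict[str, tuple]] = {
    "boltzmann": {
        "Q0": (5,),
        "alpha": (0.05, 0.1, 0.2, 0.5, 1.0),
        "tau": (1, 2, 3),
    },
    "boltzmann_ucb": {
        "Q0": (5,),
        "alpha": (0.05, 0.1, 0.2, 0.5, 1.0),
        "c": (1, 2, 3),
        "tau": (1, 2, 3),
    },
    "kalman": {
        "Q0": (5,),
        "sigma2_xi": (0.01, 0.05, 0.1, 0.2, 0.5, 1, 2),
        "sigma2_eps": (0.01, 0.05, 0.1, 0.5, 1),
        "tau": (1, 2, 3),
    },
    "kalman_iucb": {
        "Q0": (5,),
        "sigma2_xi": (0.01, 0.05, 0.1, 0.2, 0.5, 1, 2),
        "sigma2_eps": (0.01, 0.05, 0.1, 0.5, 1),
        "tau": (1, 2, 3, 4),
        "c": (1, 2, 3, 4),
    },
    "kalman_ts": {
        "Q0": (5,),
        "sigma2_xi": (0.01, 0.05, 0.1, 0.2, 0.5, 1, 2),
        "sigma2_eps": (0.01, 0.05, 0.1, 0.5, 1),
        "tau": (1, 2, 3, 4),
    },
}

#: Default hyperparameters per agent kind, frozen from this package's own
#: grid search over the TABLE4_GRIDS on a code-X synthetic database pipeline.
DEFAULT_PARAMS: dict[str, dict[str, float]] = {
    "boltzmann": {"Q0": 5, "alpha": 1.0, "tau": 2},
    "boltzmann_ucb": {"Q0": 5, "alpha": 1.0, "c": 1, "tau": 2},
    "kalman": {"Q0": 5, "sigma2_xi": 1.0, "sigma2_eps": 0.01, "tau": 2},
    "kalman_iucb": {"Q0": 5, "sigma2_xi": 0.05, "sigma2_eps": 0.01, "c": 1, "tau": 2},
    "kalman_ts": {"Q0": 5, "sigma2_xi": 0.01, "sigma2_eps": 0.01, "tau": 2},
}


@dataclass
class BanditConfig:
    """One agent's kind and hyperparameters.

    Only the parameters relevant to ``kind`` are consulted: ``alpha`` for the
    Boltzmann family, ``sigma2_xi``/``sigma2_eps`` for the Kalman family,
    ``c`` for the UCB/IUCB variants, ``tau`` and ``Q0`` always.
    """

    kind: str = "kalman_ts"
    Q0: float = 5.0
    alpha: float = 0.1
    tau: float = 2.0
    c: float = 1.0
    sigma2_xi: float = 0.1
    sigma2_eps: float = 0.1
    n_arms: int = 6
    horizon: int = 60
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in AGENT_KINDS:
            raise ValueError(f"unknown agent kind {self.kind!r}; expected one of {AGENT_KINDS}")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.c <= 0:
            raise ValueError("c must be positive")
        if self.sigma2_xi < 0 or self.sigma2_eps <= 0:
            raise ValueError("sigma2_xi must be >= 0 and sigma2_eps > 0")

    @classmethod
    def with_defaults(cls, kind: str, **overrides) -> "BanditConfig":
        """Config pre-filled with the frozen grid-search defaults for ``kind``."""
        return cls(kind=kind, **{**DEFAULT_PARAMS[kind], **overrides})


@dataclass
class BanditState:
    """Agent knowledge: reward estimates, posterior variances, pull counts."""

    mu_hat: np.ndarray
    var_hat: np.ndarray | None = None
    counts: np.ndarray = field(default_factory=lambda: np.zeros(6, dtype=int))
    t: int = 0


def init_state(config: BanditConfig) -> BanditState:
    """All estimates start at the optimistic value Q0; Kalman variances at
    sigma2_xi + sigma2_eps (a weakly informative prior on the model's own
    noise scale)."""
    mu = np.full(config.n_arms, float(config.Q0))
    var = None
    if config.kind in KALMAN_KINDS:
        var = np.full(config.n_arms, config.sigma2_xi + config.sigma2_eps)
    return BanditState(mu_hat=mu, var_hat=var,
                       counts=np.zeros(config.n_arms, dtype=int), t=0)


def softmax_probs(values: np.ndarray, tau: float) -> np.ndarray:
    """Softmax of values/tau with max-subtraction; +inf entries (forced
    exploration) receive the whole mass, split uniformly among them."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    v = np.asarray(values, dtype=float)
    if np.any(np.isposinf(v)):
        p = np.zeros_like(v)
        p[np.isposinf(v)] = 1.0
        return p / p.sum()
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite (or +inf for untried arms)")
    scaled = v / tau
    scaled -= scaled.max()
    e = np.exp(scaled)
    return e / e.sum()


def boltzmann_update(state: BanditState, arm: int, reward: float, alpha: float) -> BanditState:
    """Constant-rate exponential tracking of the pulled arm's reward."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    state.mu_hat[arm] += alpha * (reward - state.mu_hat[arm])
    state.counts[arm] += 1
    return state


def ucb_values(state: BanditState, c: float) -> np.ndarray:
    """Estimates plus the optimism bonus c*sqrt(ln t / (2 N_k)).

    Arms never pulled get an infinite bonus so each is tried once.
    """
    t = max(state.t, 1)
    bonus = np.full_like(state.mu_hat, np.inf)
    pulled = state.counts > 0
    with np.errstate(divide="ignore"):
        bonus[pulled] = c * np.sqrt(max(np.log(t), 0.0) / (2.0 * state.counts[pulled]))
    return state.mu_hat + bonus


def kalman_update(
    state: BanditState, arm: int, reward: float, sigma2_xi: float, sigma2_eps: float
) -> BanditState:
    """Sibling Kalman update: gain-weighted correction on the pulled arm,
    variance inflation by sigma2_xi on every other arm."""
    if sigma2_eps <= 0:
        raise ValueError("sigma2_eps must be positive")
    prior_var = state.var_hat + sigma2_xi
    gain = prior_var[arm] / (prior_var[arm] + sigma2_eps)
    state.mu_hat[arm] += gain * (reward - state.mu_hat[arm])
    new_var = prior_var.copy()
    new_var[arm] = (1.0 - gain) * prior_var[arm]
    state.var_hat = new_var
    state.counts[arm] += 1
    return state


def iucb_values(state: BanditState, c: float, sigma2_eps: float) -> np.ndarray:
    """Estimates plus c*sqrt(posterior variance + observation variance)."""
    if state.var_hat is None:
        raise ValueError("iucb requires a Kalman-kind state with variances")
    return state.mu_hat + c * np.sqrt(state.var_hat + sigma2_eps)


def thompson_values(
    state: BanditState, rng_seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """One Gaussian draw per arm from its posterior N(mu_hat, var_hat)."""
    if state.var_hat is None:
        raise ValueError("thompson sampling requires a Kalman-kind state with variances")
    rng = np.random.default_rng(rng_seed)
    return state.mu_hat + np.sqrt(state.var_hat) * rng.standard_normal(len(state.mu_hat))


@dataclass
class ErrorCurve:
    """Episode log: cumulative weighted-probability error plus per-iteration
    chosen arm, observed reward, probability vector and estimates."""

    ae: np.ndarray
    arms: np.ndarray
    rewards: np.ndarray
    probs: np.ndarray
    mu_hat: np.ndarray
    true_probs: np.ndarray
    true_mu: np.ndarray
    config: BanditConfig

    def final_error(self) -> float:
        return float(self.ae[-1])

    def error_at(self, T: int) -> float:
        """ae(T) for 1 <= T <= horizon."""
        return float(self.ae[T - 1])

    def to_frame(self) -> pd.DataFrame:
        k = self.probs.shape[1]
        data = {"t": np.arange(1, len(self.ae) + 1), "arm": self.arms,
                "reward": self.rewards}
        for j in range(k):
            data[f"P_{j + 1}"] = self.probs[:, j]
        for j in range(k):
            data[f"mu_{j + 1}"] = self.mu_hat[:, j]
        data["ae"] = self.ae
        return pd.DataFrame(data)


def _selection_values(state: BanditState, config: BanditConfig,
                      rng: np.random.Generator) -> np.ndarray:
    if config.kind == "boltzmann_ucb":
        return ucb_values(state, config.c)
    if config.kind == "kalman_iucb":
        return iucb_values(state, config.c, config.sigma2_eps)
    if config.kind == "kalman_ts":
        return thompson_values(state, rng)
    return state.mu_hat.copy()


def run_episode(
    config: BanditConfig,
    reward_sequence: np.ndarray,
    tau_star: float = 2.0,
    rng_seed: int | np.random.Generator | None = None,
) -> ErrorCurve:
    """Run one 60-iteration episode against a (n_arms, horizon) reward matrix.

    At each iteration the agent forms selection values per its kind, softmaxes
    them at its own temperature, samples an arm, observes that arm's true
    reward, and applies its update rule.  The evaluator concurrently forms the
    true probability vector P*(t) = softmax(mu*(t) / tau_star) from the full
    reward column and accumulates the weighted-probability error using the
    agent's pre-update estimates.
    """
    rewards = np.asarray(reward_sequence, dtype=float)
    if rewards.shape != (config.n_arms, config.horizon):
        raise ValueError(
            f"reward sequence must be ({config.n_arms}, {config.horizon}), "
            f"got {rewards.shape}"
        )
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(
        config.rng_seed if rng_seed is None else rng_seed
    )
    state = init_state(config)
    T = config.horizon
    ae = np.empty(T)
    arms = np.empty(T, dtype=int)
    obs = np.empty(T)
    probs = np.empty((T, config.n_arms))
    mu_log = np.empty((T, config.n_arms))
    p_star_log = np.empty((T, config.n_arms))
    cumulative = 0.0
    for t in range(1, T + 1):
        state.t = t
        mu_before = state.mu_hat.copy()
        values = _selection_values(state, config, rng)
        p = softmax_probs(values, config.tau)
        arm = int(rng.choice(config.n_arms, p=p))
        reward = rewards[arm, t - 1]

        mu_star = rewards[:, t - 1]
        p_star = softmax_probs(mu_star, tau_star)
        cumulative += float(np.sum(np.abs(p_star * mu_star - p * mu_before)))

        if config.kind in KALMAN_KINDS:
            kalman_update(state, arm, reward, config.sigma2_xi, config.sigma2_eps)
        else:
            boltzmann_update(state, arm, reward, config.alpha)

        i = t - 1
        ae[i] = cumulative
        arms[i] = arm
        obs[i] = reward
        probs[i] = p
        mu_log[i] = mu_before
        p_star_log[i] = p_star
    return ErrorCurve(ae=ae, arms=arms, rewards=obs, probs=probs, mu_hat=mu_log,
                      true_probs=p_star_log, true_mu=rewards.T.copy(), config=config)


def synthetic_reward_sequences(
    n_sequences: int,
    n_arms: int = 6,
    horizon: int = 60,
    rng_seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Generate non-stationary reward sequences emulating latent distances.

    Each arm's distance decays piecewise-linearly from a random start (3-8
    plane units) toward a random small floor (0-0.5) over the episode; a
    mid-episode jump (between iterations 20 and 40) re-inflates a random
    subset of 1-3 arms by 1-4 units, after which the added component decays
    linearly back out, emulating a sudden loss of motor control.  Small
    Gaussian jitter (sd 0.05) stands in for the noise replicates; values are
    clipped at zero.  Returns shape (n_sequences, n_arms, horizon).
    """
    rng = np.random.default_rng(rng_seed)
    t = np.arange(horizon)
    out = np.empty((n_sequences, n_arms, horizon))
    for s in range(n_sequences):
        start = rng.uniform(3.0, 8.0, size=n_arms)
        floor = rng.uniform(0.0, 0.5, size=n_arms)
        base = start[:, None] + (floor - start)[:, None] * t[None, :] / (horizon - 1)
        t0 = int(rng.integers(20, 41))
        jumped = rng.choice(n_arms, size=int(rng.integers(1, 4)), replace=False)
        jump = rng.uniform(1.0, 4.0, size=len(jumped))
        ramp = np.clip(1.0 - (t - t0) / (horizon - t0), 0.0, None)
        ramp[t < t0] = 0.0
        base[jumped] += jump[:, None] * ramp[None, :]
        base += rng.normal(0.0, 0.05, size=base.shape)
        out[s] = np.clip(base, 0.0, None)
    return out


def grid_search(
    param_grids: Mapping[str, Mapping[str, Sequence]],
    reward_sequences: np.ndarray,
    n_episode_seeds: int = 3,
    tau_star: float = 2.0,
    rng_seed: int = 0,
) -> tuple[dict[str, BanditConfig], pd.DataFrame]:
    """Exhaustive search of each agent kind's grid, minimising mean ae(60).

    For every parameter combination the final cumulative error is averaged
    over all supplied reward sequences and ``n_episode_seeds`` episode seeds.
    Returns the per-kind best config and the full result table.
    """
    sequences = np.asarray(reward_sequences, dtype=float)
    if sequences.ndim != 3:
        raise ValueError("reward_sequences must be (n_sequences, n_arms, horizon)")
    rows = []
    best: dict[str, BanditConfig] = {}
    for kind, grid in param_grids.items():
        if not grid or any(len(v) == 0 for v in grid.values()):
            raise ValueError(f"empty grid for agent kind {kind!r}")
        names = list(grid)
        best_err = np.inf
        for combo in itertools.product(*(grid[name] for name in names)):
            params = dict(zip(names, combo))
            config = BanditConfig(kind=kind, n_arms=sequences.shape[1],
                                  horizon=sequences.shape[2], **params)
            errs = [
                run_episode(config, seq, tau_star=tau_star,
                            rng_seed=rng_seed + 1000 * seed_i).final_error()
                for seq in sequences
                for seed_i in range(n_episode_seeds)
            ]
            mean_err, sd_err = float(np.mean(errs)), float(np.std(errs))
            rows.append({"kind": kind, **params, "mean_ae60": mean_err, "sd_ae60": sd_err})
            if mean_err < best_err:
                best_err = mean_err
                best[kind] = replace(config, rng_seed=rng_seed)
    return best, pd.DataFrame(rows)
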