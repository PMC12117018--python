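"""Stochastic exponential clone-growth simulator.

Each clone starts as one cell. Per day t the clone's size is
N_t = 2^(r_1 + ... + r_t) with i.i.d. exponential daily increments r_i
measured in population doublings, so log2(N_t) ~ Gamma(shape=t, scale=E[r]).
As t grows, log2(N_t)/t tends to a normal by the CLT — the mechanism by
which a mixture of growth-rate subpopulations produces a mixture of
near-Gaussian doubling-time components.

By default increments are drawn with E[r_i] = 1/mu doublings per day so the
realized doubling time t/log2(N_t) concentrates at the configured mean
doubling time mu. ``literal_rate=True`` instead draws r_i ~ Exp(rate=1/mu)
(mean mu doublings per day), the alternative reading of the model's rate
parameter.

Growth stops at a population cap (default 10^7 cells, the maximum
permissible tumour size) or a time cap (10^3 days); the increment that
crosses the cap is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from clonetrack.exceptions import ConfigError


@dataclass
class SimulationLimits:
    """Stopping rules: cell capacity and maximum simulated days."""

    max_cells: float = 1e7
    max_days: int = 1000

    def __post_init__(self):
        if self.max_cells <= 0 or self.max_days <= 0:
            raise ConfigError("limits must be positive")


@dataclass
class SubpopulationSpec:
    """A growth-rate subpopulation: mean doubling time mu (days) and weight."""

    mu: float
    weight: float
    label: str = ""

    def __post_init__(self):
        if self.mu <= 0:
            raise ConfigError("mean doubling time must be positive")
        if not 0 <= self.weight <= 1:
            raise ConfigError("weight must be in [0, 1]")


@dataclass
class CloneTrajectory:
    log2_sizes: np.ndarray  # log2(N_t) for t = 0..T
    final_size: float
    days: int
    realized_doubling_time: float


def _increment_scale(mu: float, literal_rate: bool) -> float:
    # scale = E[r_i] in doublings/day
    return mu if literal_rate else 1.0 / mu


def simulate_clone_trajectory(
    mu: float,
    limits: SimulationLimits | None = None,
    seed: int = 0,
    literal_rate: bool = False,
) -> CloneTrajectory:
    """Grow a single clone from one cell under the exponential-increment model."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    limits = limits or SimulationLimits()
    rng = np.random.default_rng(seed)
    scale = _increment_scale(mu, literal_rate)
    log2n = [0.0]
    log2cap = np.log2(limits.max_cells)
    t = 0
    while t < limits.max_days and log2n[-1] < log2cap:
        t += 1
        log2n.append(log2n[-1] + rng.exponential(scale))
    log2_sizes = np.array(log2n)
    final = float(2 ** log2_sizes[-1])
    dt = t / log2_sizes[-1] if log2_sizes[-1] > 0 else np.inf
    return CloneTrajectory(
        log2_sizes=log2_sizes, final_size=final, days=t,
        realized_doubling_time=float(dt),
    )


def simulate_population(
    specs: list[SubpopulationSpec],
    n_clones: int,
    limits: SimulationLimits | None = None,
    seed: int = 0,
    cap: str = "population",
    literal_rate: bool = False,
) -> pd.DataFrame:
    """Grow ``n_clones`` clones drawn from growth-rate subpopulations.

    Clones are assigned to subpopulations by weight and grown independently,
    day by day. With ``cap='population'`` (the default) the simulation stops
    when the summed cell count reaches the capacity — mimicking the maximum
    tumour size — or at the time cap; ``cap='clone'`` instead freezes each
    clone individually once it reaches the capacity.

    Returns one row per clone: subpopulation label, true mu, days grown,
    log2 final size, final size and realized doubling time — ready for
    :func:`clonetrack.metrics.fit_doubling_mixture`.
    """
    if not specs:
        raise ConfigError("need at least one subpopulation spec")
    if n_clones <= 0:
        raise ValueError("n_clones must be positive")
    weights = np.array([s.weight for s in specs], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ConfigError(f"subpopulation weights sum to {weights.sum()}, not 1")
    if cap not in ("population", "clone"):
        raise ValueError("cap must be 'population' or 'clone'")
    limits = limits or SimulationLimits()
    rng = np.random.default_rng(seed)
    assignment = rng.choice(len(specs), size=n_clones, p=weights)
    scales = np.array([_increment_scale(s.mu, literal_rate) for s in specs])
    clone_scale = scales[assignment]
    log2n = np.zeros(n_clones)
    days = np.zeros(n_clones, dtype=int)
    log2cap = np.log2(limits.max_cells)
    active = np.ones(n_clones, dtype=bool)
    for t in range(1, limits.max_days + 1):
        inc = rng.exponential(clone_scale[active])
        log2n[active] += inc
        days[active] = t
        if cap == "clone":
            active &= log2n < log2cap
            if not active.any():
                break
        else:
            # population-level capacity: stop everything once total cells
            # reach the cap (the crossing day's increments are kept)
            m = log2n.max()
            total = (2 ** (log2n - m)).sum() * 2**m
            if total >= limits.max_cells:
                break
    grown = log2n > 0
    dt = np.full(n_clones, np.inf)
    dt[grown] = days[grown] / log2n[grown]
    labels = [specs[i].label or f"subpop{i}" for i in assignment]
    return pd.DataFrame(
        {
            "subpopulation": labels,
            "true_mu": np.array([s.mu for s in specs])[assignment],
            "days": days,
            "log2_size": log2n,
            "final_size": 2.0**log2n,
            "doubling_time": dt,
        }
    )


def gamma_limit_stats(t: int, rate: float) -> dict[str, float]:
    """CLT mean and variance of log2(N_t)/t for increments r_i ~ Exp(rate).

    log2(N_t) ~ Gamma(shape=t, scale=1/rate), so log2(N_t)/t has mean 1/rate
    and variance 1/(t * rate^2), approaching a normal as t -> infinity.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if rate <= 0:
        raise ValueError("rate must be positive")
    return {"mean": 1.0 / rate, "variance": 1.0 / (t * rate**2)}
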