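"""Adjusting-amount delay discounting task (ADDT) simulator.

The task presents a choice between a smaller immediate reward and a larger
delayed reward (default $100) at seven delays (6 h .. 5 y).  Within each
delay block the immediate amount is titrated over six choices: it starts at
half the delayed amount and is halved-step adjusted after every choice —
down if the immediate option was taken, up if the delayed option was taken.
The indifference point (IP) recorded for the block is the immediate amount
after the sixth choice, corrected by half the final step in the direction of
that choice.  For a deterministic agent with a monotone value function this
is exact bisection, so the IP is within A/2**7 of the true present value.

Agents are either hyperbolic discounters valuing the delayed reward at
``A / (1 + k*D)`` with a logistic choice rule, or non-systematic responders
choosing uniformly at random on every trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

#: Delays in days for the seven blocks: 6 h, 1 d, 1 wk, 1 mo, 3 mo, 1 y, 5 y.
#: Calendar conversions: 1 month = 30 d, 1 year = 365 d.
DEFAULT_DELAYS_DAYS: tuple[float, ...] = (0.25, 1.0, 7.0, 30.0, 90.0, 365.0, 1825.0)


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the adjusting-amount staircase."""

    delayed_amount: float = 100.0
    initial_immediate: float = 50.0
    delays: tuple[float, ...] = DEFAULT_DELAYS_DAYS
    choices_per_block: int = 6

    def __post_init__(self) -> None:
        d = np.asarray(self.delays, dtype=float)
        if d.ndim != 1 or len(d) < 2:
            raise ValueError("delays must be a 1-d sequence of length >= 2")
        if not (np.all(np.diff(d) > 0) and np.all(d > 0)):
            raise ValueError("delays must be strictly increasing and positive")
        if not 0 < self.initial_immediate < self.delayed_amount:
            raise ValueError("initial_immediate must lie in (0, delayed_amount)")
        if self.choices_per_block < 1:
            raise ValueError("choices_per_block must be >= 1")

    @property
    def resolution(self) -> float:
        """Half the final adjustment step: A / 2**(choices_per_block + 1)."""
        return self.delayed_amount / 2 ** (self.choices_per_block + 1)


@dataclass(frozen=True)
class Agent:
    """A simulated respondent.

    kind
        ``"hyperbolic"`` — values the delayed reward at ``A/(1 + k*D)`` and
        chooses the delayed option with probability
        ``expit(inverse_temp * (A/(1+kD) - immediate))``;
        ``inverse_temp = inf`` gives a deterministic agent (ties -> delayed).
    kind ``"random"`` — ignores amounts; each choice is a fair coin flip.
    """

    kind: str = "hyperbolic"
    k: float | None = None
    inverse_temp: float = np.inf

    def __post_init__(self) -> None:
        if self.kind not in ("hyperbolic", "random"):
            raise ValueError(f"unknown agent kind {self.kind!r}")
        if self.kind == "hyperbolic":
            if self.k is None or self.k <= 0:
                raise ValueError("hyperbolic agent requires k > 0")
        if self.inverse_temp < 0:
            raise ValueError("inverse_temp must be >= 0")


@dataclass
class IndifferenceProfile:
    """Per-subject delay -> indifference point curve, in ascending-delay order."""

    subject_id: str
    delays: np.ndarray
    indifference_points: np.ndarray
    delayed_amount: float = 100.0

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.indifference_points = np.asarray(self.indifference_points, dtype=float)
        if self.delays.shape != self.indifference_points.shape:
            raise ValueError("delays and indifference_points must have equal length")
        if np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be strictly increasing")
        if np.any((self.indifference_points < 0) | (self.indifference_points > self.delayed_amount)):
            raise ValueError("indifference points must lie in [0, delayed_amount]")


def hyperbolic_value(amount: float, k: float, delay: float) -> float:
    """Present value A * g(D) with g(D) = 1 / (1 + k*D)."""
    return amount / (1.0 + k * delay)


def _p_delayed(agent: Agent, immediate: float, delay: float, amount: float) -> float:
    if agent.kind == "random":
        return 0.5
    v = hyperbolic_value(amount, agent.k, delay)
    if np.isinf(agent.inverse_temp):
        return 1.0 if v >= immediate else 0.0
    return float(expit(agent.inverse_temp * (v - immediate)))


def run_adjusting_block(
    agent: Agent, delay: float, config: TaskConfig = TaskConfig(), rng=None
) -> tuple[np.ndarray, float]:
    """Run one staircase block; return (choice sequence, indifference point).

    Choices are coded 1 = delayed option, 0 = immediate option.  The
    immediate amount starts at A/2; after choice t (t = 1..m-1) it moves by
    A/2**(t+1), up if the delayed reward was chosen and down otherwise.  The
    IP is the immediate amount after choice m, corrected by half the final
    step (A/2**(m+1)) in the direction of that last choice.
    """
    if delay <= 0:
        raise ValueError("delay must be positive")
    rng = np.random.default_rng(rng)
    A = config.delayed_amount
    m = config.choices_per_block
    immediate = config.initial_immediate
    choices = np.empty(m, dtype=np.int8)
    for t in range(1, m + 1):
        p = _p_delayed(agent, immediate, delay, A)
        choose_delayed = p == 1.0 or (p > 0.0 and rng.random() < p)
        choices[t - 1] = choose_delayed
        step = A / 2 ** (t + 1)
        immediate += step if choose_delayed else -step
    return choices, immediate


def simulate_task(
    agent: Agent, config: TaskConfig = TaskConfig(), seed=None, subject_id: str = "s0"
) -> IndifferenceProfile:
    """Administer all blocks in a seeded random order; profile is returned
    sorted by ascending delay regardless of administration order."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(config.delays))
    ips = np.empty(len(config.delays))
    for block in order:
        _, ips[block] = run_adjusting_block(agent, config.delays[block], config, rng)
    return IndifferenceProfile(
        subject_id=subject_id,
        delays=np.asarray(config.delays, dtype=float),
        indifference_points=ips,
        delayed_amount=config.delayed_amount,
    )


def simulate_profiles(
    k: np.ndarray,
    nonsystematic: np.ndarray,
    inverse_temp: float = np.inf,
    config: TaskConfig = TaskConfig(),
    seed=None,
    subject_ids=None,
) -> pd.DataFrame:
    """Vectorised task simulation for a whole cohort.

    Runs the same staircase as :func:`run_adjusting_block` for every subject
    and delay at once.  Because choices are conditionally independent given
    the agent, block administration order does not affect the distribution of
    profiles and blocks are processed in ascending-delay order here.

    Returns a long DataFrame (subject_id, delay_days, indifference_point).
    """
    rng = np.random.default_rng(seed)
    k = np.asarray(k, dtype=float)
    nonsys = np.asarray(nonsystematic, dtype=bool)
    n = len(k)
    if subject_ids is None:
        subject_ids = [f"s{i:05d}" for i in range(n)]
    delays = np.asarray(config.delays, dtype=float)
    A = config.delayed_amount
    m = config.choices_per_block
    u = rng.random((n, len(delays), m))
    ips = np.empty((n, len(delays)))
    for j, D in enumerate(delays):
        immediate = np.full(n, config.initial_immediate)
        v = A / (1.0 + k * D)
        for t in range(1, m + 1):
            if np.isinf(inverse_temp):
                p = (v >= immediate).astype(float)
            else:
                p = expit(inverse_temp * (v - immediate))
            p = np.where(nonsys, 0.5, p)
            choose_delayed = u[:, j, t - 1] < p
            # deterministic ties (p exactly 1/0) are unaffected: u in [0,1)
            step = A / 2 ** (t + 1)
            immediate += np.where(choose_delayed, step, -step)
        ips[:, j] = immediate
    out = pd.DataFrame(
        {
            "subject_id": np.repeat(subject_ids, len(delays)),
            "delay_days": np.tile(delays, n),
            "indifference_point": ips.ravel(),
        }
    )
    return out


def profiles_from_frame(df: pd.DataFrame, delayed_amount: float = 100.0):
    """Yield IndifferenceProfile objects from a long (subject_id, delay_days,
    indifference_point) table."""
    for sid, g in df.groupby("subject_id", sort=True):
        g = g.sort_values("delay_days")
        yield IndifferenceProfile(
            subject_id=str(sid),
            delays=g["delay_days"].to_numpy(),
            indifference_points=g["indifference_point"].to_numpy(),
            delayed_amount=delayed_amount,
        )


def write_profiles_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_profiles_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
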