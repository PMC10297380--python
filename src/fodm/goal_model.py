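"""Goal-attainment probability: P = 1 - (1-p)^k.

The chance of at least one success in k independent repetitions of an
elementary event with probability p, its inverse (repetitions needed for a
target P), and a seeded Monte-Carlo verifier.
"""

from __future__ import annotations

import math

import numpy as np


def goal_probability(p: float, k: int) -> float:
    """P = 1 - (1-p)^k for k independent trials of probability p."""
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must be in (0, 1], got {p}")
    if not (isinstance(k, (int, np.integer)) and k >= 1):
        raise ValueError(f"k must be a positive integer, got {k}")
    return 1.0 - (1.0 - p) ** k


def required_repetitions(p: float, target_P: float) -> int:
    """Smallest k with 1 - (1-p)^k >= target_P.

    Closed form ceil(ln(1-target_P)/ln(1-p)) with a one-step integer check to
    guard against floating-point boundary slips.
    """
    if p == 1.0:
        return 1
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must be in (0, 1), got {p}")
    if not (0.0 < target_P < 1.0):
        raise ValueError(f"target_P must be in (0, 1), got {target_P} "
                         "(P = 1 is unreachable for p < 1)")
    k = max(1, math.ceil(math.log(1.0 - target_P) / math.log(1.0 - p)))
    while k > 1 and goal_probability(p, k - 1) >= target_P:
        k -= 1
    while goal_probability(p, k) < target_P:
        k += 1
    return k


def simulate_goal(p: float, k: int, trials: int, seed: int,
                  _chunk: int = 1_000_000) -> float:
    """Empirical fraction of trials with >= 1 success among k Bernoulli(p) draws."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    if k < 1 or trials < 1:
        raise ValueError("k and trials must be >= 1")
    rng = np.random.default_rng(seed)
    hits = 0
    per_chunk = max(1, _chunk // k)
    done = 0
    while done < trials:
        m = min(per_chunk, trials - done)
        draws = rng.random((m, k)) < p
        hits += int(draws.any(axis=1).sum())
        done += m
    return hits / trials
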