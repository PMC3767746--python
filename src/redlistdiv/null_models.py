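"""Tip-shuffle null models, rank p-values and the three-way verdict.

The observed branch-sum diversity of a species set is compared with a
null distribution obtained by drawing equally many tips uniformly
without replacement from a species pool on the same tree (equivalent
to shuffling taxon labels across the pool's tips while holding
richness fixed).  The p-value is the rank of the observed value among
observed + nulls divided by (number of nulls + 1); ties contribute
half a rank by default, so a degenerate zero-variance null yields
p = 0.5 and the verdict "equal".

Verdicts: "lower" when p <= 0.025 (the set spans significantly less
diversity than random draws, i.e. clustering), "higher" when
p >= 0.975 (overdispersion), "equal" otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .diversity import SubtreeCalculator

__all__ = [
    "NullResult",
    "rank_p_value",
    "classify_deviation",
    "tip_shuffle_null",
    "LOWER",
    "EQUAL",
    "HIGHER",
]

LOWER = "lower"
EQUAL = "equal"
HIGHER = "higher"

DEFAULT_N_REPS = 999
DEFAULT_P_LOW = 0.025
DEFAULT_P_HIGH = 0.975


@dataclass
class NullResult:
    observed: float
    null_values: np.ndarray
    p: float
    ses: float
    classification: str
    n_reps: int
    seed: int
    degenerate_null: bool = field(default=False)

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_values, ddof=1)) if self.n_reps > 1 else 0.0


def rank_p_value(observed: float, null_values: np.ndarray, ties: str = "midrank") -> float:
    """Rank of the observed value among observed + nulls, over (n + 1).

    ``ties="midrank"`` (default) counts each tied null as half a rank;
    ``ties="minrank"`` counts none of them, giving the smallest
    consistent rank.
    """
    nulls = np.asarray(null_values, dtype=float)
    n = nulls.size
    if n < 1:
        raise ValueError("need at least one null value")
    below = int(np.count_nonzero(nulls < observed))
    tied = int(np.count_nonzero(nulls == observed))
    if ties == "midrank":
        rank = below + 0.5 * tied + 1
    elif ties == "minrank":
        rank = below + 1
    else:
        raise ValueError(f"unknown tie rule: {ties!r}")
    return rank / (n + 1)


def classify_deviation(
    p: float, low: float = DEFAULT_P_LOW, high: float = DEFAULT_P_HIGH
) -> str:
    """Three-way verdict from a rank p-value (boundaries inclusive)."""
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must be in (0, 1], got {p}")
    if p <= low:
        return LOWER
    if p >= high:
        return HIGHER
    return EQUAL


def tip_shuffle_null(
    tree: dendropy.Tree | SubtreeCalculator,
    tips: set[str] | list[str],
    pool: set[str] | list[str],
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
    include_root: bool = True,
    ties: str = "midrank",
    p_low: float = DEFAULT_P_LOW,
    p_high: float = DEFAULT_P_HIGH,
) -> NullResult:
    """Null distribution of branch-sum diversity under label shuffling.

    ``tree`` may be a pre-built :class:`SubtreeCalculator` when many
    cells are scored against one tree.  Each replicate draws
    ``len(tips)`` labels uniformly without replacement from ``pool``.
    Reproducible for a given ``seed``.
    """
    calc = tree if isinstance(tree, SubtreeCalculator) else SubtreeCalculator(tree)
    tips = sorted(set(tips))
    pool = sorted(set(pool))
    if len(tips) < 1:
        raise ValueError("empty tip set")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not set(tips) <= set(pool):
        raise ValueError("tips must be a subset of the pool")
    pool_idx = calc.rows(pool)  # also validates membership in tree
    tip_idx = calc.rows(tips)
    k, m = len(tips), len(pool)
    if k > m:
        raise ValueError("pool smaller than tip set")

    observed = float(calc.values_many(tip_idx[None, :], include_root)[0])
    rng = np.random.default_rng(seed)
    # R draws of k from m without replacement: argpartition of uniforms
    u = rng.random((n_reps, m))
    draws = pool_idx[np.argpartition(u, k - 1, axis=1)[:, :k]]
    null_values = calc.values_many(draws, include_root)

    p = rank_p_value(observed, null_values, ties=ties)
    sd = float(np.std(null_values, ddof=1)) if n_reps > 1 else 0.0
    degenerate = sd == 0.0
    ses = 0.0 if degenerate else (observed - float(np.mean(null_values))) / sd
    return NullResult(
        observed=observed,
        null_values=null_values,
        p=p,
        ses=ses,
        classification=classify_deviation(p, p_low, p_high),
        n_reps=n_reps,
        seed=seed,
        degenerate_null=degenerate,
    )
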