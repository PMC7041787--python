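"""Monte-Carlo set-sampling engine for overlap and exceedance nulls.

Draws gene sets uniformly without replacement from a universe and compares
a statistic of each draw with the observed value.  The p-value uses the
add-one convention p = (n_at_least + 1) / (n_iter + 1), so it can never be
exactly zero, and "at least as extreme" means >= the observed statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .errors import ConfigError


@dataclass
class PermutationResult:
    observed: float
    n_iter: int
    n_at_least: int
    p: float
    seed: int

    def __post_init__(self) -> None:
        expected = (self.n_at_least + 1) / (self.n_iter + 1)
        if not np.isclose(self.p, expected):
            raise ConfigError("p must equal (n_at_least + 1) / (n_iter + 1)")


def _check(universe, draw_size, n_iter):
    if n_iter < 1:
        raise ConfigError("n_iter must be >= 1")
    if draw_size > len(universe):
        raise ConfigError("draw_size exceeds universe size")


def overlap_permutation(
    universe,
    draw_size: int,
    target,
    n_iter: int = 10_000,
    seed: int = 0,
    drawn_set=None,
    observed: int | None = None,
) -> PermutationResult:
    """Null distribution of |random draw ∩ target|.

    The observed overlap comes from ``drawn_set`` when a concrete set is
    given, else from ``observed``.  Target members outside the universe are
    dropped with a warning.
    """
    universe = sorted(set(universe))
    _check(universe, draw_size, n_iter)
    target = set(target)
    stray = target - set(universe)
    if stray:
        warnings.warn(
            f"{len(stray)} target gene(s) outside the universe were ignored",
            stacklevel=2,
        )
        target &= set(universe)
    if drawn_set is not None:
        observed = len(set(drawn_set) & target)
    elif observed is None:
        raise ConfigError("provide either drawn_set or observed")

    idx = {g: i for i, g in enumerate(universe)}
    mask = np.zeros(len(universe), dtype=bool)
    mask[[idx[g] for g in target]] = True
    rng = np.random.default_rng([seed, 0x0F])
    n_at_least = 0
    for _ in range(n_iter):
        draw = rng.choice(len(universe), size=draw_size, replace=False)
        if int(mask[draw].sum()) >= observed:
            n_at_least += 1
    p = (n_at_least + 1) / (n_iter + 1)
    return PermutationResult(observed=float(observed), n_iter=n_iter,
                             n_at_least=n_at_least, p=p, seed=seed)


def exceedance_permutation(
    universe,
    draw_size: int,
    statistic,
    observed_count: float,
    n_iter: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Null for an arbitrary per-set count statistic.

    ``statistic`` maps a tuple of drawn ids to a number (e.g. how many drawn
    genes pass a drug-response ANOVA at 0.05); the engine is agnostic to the
    contract.
    """
    universe = sorted(set(universe))
    _check(universe, draw_size, n_iter)
    arr = np.array(universe, dtype=object)
    rng = np.random.default_rng([seed, 0x0E])
    n_at_least = 0
    for _ in range(n_iter):
        draw = arr[rng.choice(len(arr), size=draw_size, replace=False)]
        if statistic(tuple(draw)) >= observed_count:
            n_at_least += 1
    p = (n_at_least + 1) / (n_iter + 1)
    return PermutationResult(observed=float(observed_count), n_iter=n_iter,
                             n_at_least=n_at_least, p=p, seed=seed)


def count_in_set_statistic(flagged) -> "callable":
    """Statistic contract counting how many drawn ids fall in ``flagged``."""
    flagged = frozenset(flagged)
    def stat(draw) -> int:
        return sum(1 for g in draw if g in flagged)
    return stat
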