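"""Resampling inference: island permutation tests, percentile bootstraps,
and two-sample t-tests.

These are the constructed inference tools used throughout the island
comparisons.  The permutation test relabels whole sampling units (an
individual monkey's tools travel together), the bootstrap is the plain
percentile interval of a mean, and the t-test defaults to the Welch
(unequal-variance) form with the Welch-Satterthwaite degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PermutationResult",
    "BootstrapCI",
    "TestResult",
    "permutation_island_test",
    "bootstrap_mean_ci",
    "bootstrap_group_compare",
    "welch_t_test",
    "student_t_test",
]


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic with its relabelling null distribution."""

    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    n_perm: int
    unit: str
    seed: int | None
    exhaustive: bool = False

    def __post_init__(self) -> None:
        assert 0.0 < self.p_value <= 1.0


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile bootstrap confidence interval for a sample mean."""

    point: float
    lower: float
    upper: float
    level: float = 0.95
    n_boot: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        assert self.lower <= self.upper

    def overlaps(self, other: "BootstrapCI") -> bool:
        return self.lower <= other.upper and other.lower <= self.upper


@dataclass(frozen=True)
class TestResult:
    """A classical test statistic with its degrees of freedom and p-value."""

    statistic: float
    df: float
    p_value: float
    kind: str = "t_welch"

    @property
    def df_int(self) -> int:
        """Degrees of freedom rounded to the nearest integer for display."""
        return int(round(self.df))


def _group_indices(
    islands: Sequence, unit_ids: Sequence | None, unit: str
) -> tuple[list[np.ndarray], np.ndarray]:
    """Unit membership (record indices per unit) and per-unit island labels."""
    islands = np.asarray([str(i) for i in islands])
    if unit == "record" or unit_ids is None:
        members = [np.array([i]) for i in range(len(islands))]
        labels = islands
    elif unit == "individual":
        ids = np.asarray([str(u) for u in unit_ids])
        members, labels = [], []
        for uid in pd.unique(ids):
            idx = np.flatnonzero(ids == uid)
            isl = set(islands[idx])
            if len(isl) != 1:
                raise ValueError(f"unit {uid!r} spans multiple islands: {isl}")
            members.append(idx)
            labels.append(islands[idx[0]])
        labels = np.asarray(labels)
    else:
        raise ValueError(f"unknown permutation unit {unit!r}")
    return members, labels


def permutation_island_test(
    data: pd.DataFrame,
    stat_fn: Callable[[pd.DataFrame], float],
    n_perm: int = 10000,
    unit: str = "individual",
    seed: int | None = None,
    island_col: str = "island",
    unit_col: str = "user_id",
) -> PermutationResult:
    """Two-sided permutation test of an island effect.

    The island label is randomly reassigned at the level of whole sampling
    units (all records of one individual move together when
    ``unit='individual'``), keeping the number of units per island fixed.
    The two-sided p-value uses the add-one estimator
    ``p = (#{|null| >= |observed|} + 1) / (n_perm + 1)``.

    When the number of distinct unit-level relabelings is at most ``n_perm``
    the test enumerates them exhaustively and reports the exact p-value
    ``#{|null| >= |observed|} / n_assignments`` (the identity relabeling is
    one of them, so p > 0).
    """
    islands = data[island_col]
    unit_ids = data[unit_col] if (unit == "individual" and unit_col in data) else None
    members, labels = _group_indices(islands, unit_ids, unit)
    levels = pd.unique(labels)
    if len(levels) < 2:
        raise ValueError("permutation test needs records from both islands")
    n_units = len(members)
    n_a = int(np.sum(labels == levels[0]))
    if n_a < 2 or n_units - n_a < 2:
        raise ValueError("need at least 2 units per island")

    observed = float(stat_fn(data))

    def _stat_for(assignment_a: np.ndarray) -> float:
        new_labels = np.full(n_units, levels[1], dtype=object)
        new_labels[assignment_a] = levels[0]
        relabelled = np.empty(len(data), dtype=object)
        for u, lab in enumerate(new_labels):
            relabelled[members[u]] = lab
        shuffled = data.copy()
        shuffled[island_col] = relabelled
        return float(stat_fn(shuffled))

    n_total = math.comb(n_units, n_a)
    if n_total <= n_perm:
        null = np.empty(n_total)
        for k, combo in enumerate(combinations(range(n_units), n_a)):
            try:
                null[k] = _stat_for(np.asarray(combo))
            except Exception as err:  # pragma: no cover - diagnostic path
                raise RuntimeError(f"stat_fn failed on relabeling {k}") from err
        p = float(np.mean(np.abs(null) >= abs(observed) - 1e-12))
        return PermutationResult(observed, null, p, n_total, unit, seed, True)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        assignment = rng.choice(n_units, size=n_a, replace=False)
        try:
            null[k] = _stat_for(assignment)
        except Exception as err:
            raise RuntimeError(f"stat_fn failed on relabeling {k}") from err
    p = float((np.sum(np.abs(null) >= abs(observed) - 1e-12) + 1) / (n_perm + 1))
    return PermutationResult(observed, null, p, n_perm, unit, seed, False)


def bootstrap_mean_ci(
    values: Sequence[float],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> BootstrapCI:
    """Percentile bootstrap CI for the mean.

    Resamples ``n_boot`` times with replacement at the original sample size
    using ``numpy.random.default_rng(seed).integers(0, n, size=(n_boot, n))``
    as the index stream, then takes the ``(1-level)/2`` and ``1-(1-level)/2``
    quantiles (``numpy.quantile``, linear interpolation) of the resampled
    means.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("bootstrap needs at least one value")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return BootstrapCI(float(values.mean()), float(lo), float(hi), level, n_boot, seed)


def bootstrap_group_compare(
    a: Sequence[float],
    b: Sequence[float],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[BootstrapCI, BootstrapCI, bool]:
    """Bootstrap both group means and report whether the CIs intersect.

    The two groups use independent substreams spawned from ``seed`` so that
    the verdict is symmetric in the pair and reproducible.
    """
    ss = np.random.SeedSequence(seed)
    child_a, child_b = ss.spawn(2)
    ci_a = bootstrap_mean_ci(a, n_boot, level, seed=child_a.generate_state(1)[0] % (2**31))
    ci_b = bootstrap_mean_ci(b, n_boot, level, seed=child_b.generate_state(1)[0] % (2**31))
    return ci_a, ci_b, ci_a.overlaps(ci_b)


def _two_sample_t(a, b, equal_var: bool) -> TestResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both groups have zero variance; t is undefined")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = a.size + b.size - 2.0
        kind = "t_student"
    else:
        sa, sb = va / a.size, vb / b.size
        df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
        kind = "t_welch"
    return TestResult(float(t), float(df), float(p), kind)


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Welch two-sample t-test (unequal variances), two-sided."""
    return _two_sample_t(a, b, equal_var=False)


def student_t_test(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Pooled-variance two-sample t-test, two-sided."""
    return _two_sample_t(a, b, equal_var=True)
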