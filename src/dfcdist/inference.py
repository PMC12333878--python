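"""Sex-stratified, age-residualized permutation testing of group differences.

For one (metric, contrast, sex, test type) cell: the per-subject summary
statistic (mean or 5-peak value of the distance series) is residualized on
age by an ordinary least-squares fit with intercept, pooled across the two
diagnostic groups of the sex stratum.  The observed statistic is the
absolute difference of group means of the residuals,

    T_obs = |mean(x) - mean(y)|,

and its null distribution is built by randomly reassigning the pooled
residuals into groups of the original sizes; the two-tailed p-value is the
fraction of permuted statistics at least as large as the observed one,

    p = (1/B) * sum_b I(T(b) >= T_obs).

The estimator is unsmoothed (it can return 0); ``smooth=True`` switches to
(1 + count) / (1 + B) for users who need a strictly positive p.  When the
number of distinct group assignments C(m+n, m) is at most 10,000 the test
enumerates all of them exactly instead of sampling.

Bonferroni correction divides the family-wise level (default 0.05) by the
number of tests per metric family (default 8 = 2 contrasts x 2 sexes x
2 test types); decisions use the exact threshold with a non-strict
comparison (p equal to the threshold counts as significant).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from math import comb
from itertools import combinations

import numpy as np
import pandas as pd

from ._errors import ConfigError, DataError

__all__ = [
    "ComparisonSpec",
    "PermutationResult",
    "ComparisonResult",
    "regress_out_age",
    "permutation_test",
    "run_comparison",
    "bonferroni_threshold",
]

EXHAUSTIVE_LIMIT = 10_000
TEST_TYPES = ("mean_based", "peak_based")


@dataclass(frozen=True)
class ComparisonSpec:
    """One cell of the experiment grid."""

    contrast: tuple[str, str]
    sex: str
    test_type: str
    metric_name: str
    n_permutations: int = 50_000
    seed: int = 0
    family_alpha: float = 0.05
    family_size: int = 8
    smooth_p: bool = False
    exhaustive: bool | str = "auto"

    def __post_init__(self) -> None:
        if self.contrast[0] == self.contrast[1]:
            raise ConfigError("contrast labels must be distinct")
        if self.test_type not in TEST_TYPES:
            raise ConfigError(f"test_type must be one of {TEST_TYPES}")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if not (0 < self.family_alpha < 1):
            raise ConfigError("family_alpha must lie in (0, 1)")
        if self.family_size < 1:
            raise ConfigError("family_size must be >= 1")


@dataclass
class PermutationResult:
    t_obs: float
    p_value: float
    n_permutations: int
    group_sizes: tuple[int, int]
    exhaustive: bool
    permuted_stats_digest: dict[str, float] = field(default_factory=dict)


@dataclass
class ComparisonResult:
    spec: ComparisonSpec
    permutation: PermutationResult
    bonferroni_threshold: float

    @property
    def p_value(self) -> float:
        return self.permutation.p_value

    @property
    def significant(self) -> bool:
        return self.p_value <= self.bonferroni_threshold


def regress_out_age(values, ages) -> np.ndarray:
    """Residuals of an OLS fit (with intercept) of the summary values on age.

    The fit is computed once on the pooled sample it is given; residuals sum
    to ~0 and are orthogonal to centered age.
    """
    v = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if v.shape != a.shape or v.ndim != 1:
        raise DataError("values and ages must be 1-D and of equal length")
    if len(v) < 3:
        raise DataError("age regression needs at least 3 subjects")
    if np.ptp(a) == 0:
        raise DataError("ages are constant; age regression is undefined")
    design = np.column_stack([np.ones_like(a), a])
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def _digest(stats: np.ndarray) -> dict[str, float]:
    qs = np.quantile(stats, [0.5, 0.9, 0.95, 0.99])
    return {
        "q50": float(qs[0]),
        "q90": float(qs[1]),
        "q95": float(qs[2]),
        "q99": float(qs[3]),
        "max": float(stats.max()),
    }


def permutation_test(
    x,
    y,
    n_permutations: int = 50_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    exhaustive: bool | str = "auto",
    smooth: bool = False,
) -> PermutationResult:
    """Two-tailed permutation test of a difference in group means.

    ``exhaustive="auto"`` enumerates all C(m+n, m) assignments when there
    are at most 10,000 of them; otherwise ``n_permutations`` uniform random
    reassignments are sampled (with replacement across iterations).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise DataError(f"both groups must be non-empty (sizes {m}, {n})")
    z = np.concatenate([x, y])
    total = z.sum()
    # T_obs through the same sum-based formula used for permuted statistics,
    # so identical assignments compare exactly equal.
    t_obs = abs(z[:m].sum() / m - (total - z[:m].sum()) / n)

    # counting threshold with a relative slack so assignments whose statistic
    # ties T_obs in exact arithmetic are counted despite round-off
    thresh = t_obs - 1e-12 * max(1.0, abs(t_obs))

    n_distinct = comb(m + n, m)
    use_exhaustive = exhaustive is True or (
        exhaustive == "auto" and n_distinct <= EXHAUSTIVE_LIMIT
    )
    if use_exhaustive:
        idx = np.fromiter(
            (i for combo in combinations(range(m + n), m) for i in combo),
            dtype=np.intp,
            count=n_distinct * m,
        ).reshape(n_distinct, m)
        sx = z[idx].sum(axis=1)
        stats = np.abs(sx / m - (total - sx) / n)
        count = int((stats >= thresh).sum())
        b_eff = n_distinct
        digest = _digest(stats)
    else:
        if rng is None:
            rng = np.random.default_rng(seed)
        b_eff = int(n_permutations)
        count = 0
        digest_chunks = []
        done = 0
        while done < b_eff:
            block = min(10_000, b_eff - done)
            order = np.argsort(rng.random((block, m + n)), axis=1)
            sx = z[order[:, :m]].sum(axis=1)
            stats = np.abs(sx / m - (total - sx) / n)
            count += int((stats >= thresh).sum())
            digest_chunks.append(stats)
            done += block
        digest = _digest(np.concatenate(digest_chunks))
    if smooth:
        p = (1 + count) / (1 + b_eff)
    else:
        p = count / b_eff
    return PermutationResult(
        t_obs=float(t_obs),
        p_value=float(p),
        n_permutations=b_eff,
        group_sizes=(m, n),
        exhaustive=use_exhaustive,
        permuted_stats_digest=digest,
    )


def bonferroni_threshold(family_alpha: float, family_size: int) -> float:
    """Per-comparison significance threshold family_alpha / family_size."""
    if family_size < 1:
        raise ConfigError("family_size must be >= 1")
    return family_alpha / family_size


def comparison_seed(root_seed: int, spec: ComparisonSpec) -> np.random.SeedSequence:
    """Deterministic per-cell seed so results do not depend on the order in
    which grid cells are executed."""
    key = "|".join(
        [spec.metric_name, spec.contrast[0], spec.contrast[1], spec.sex, spec.test_type]
    )
    return np.random.SeedSequence([int(root_seed), zlib.crc32(key.encode())])


def run_comparison(
    summaries: pd.DataFrame, metadata: pd.DataFrame, spec: ComparisonSpec
) -> ComparisonResult:
    """Run one grid cell on a summary table joined to subject metadata.

    ``summaries`` needs columns subject_id, metric, mean_value, peak_value;
    ``metadata`` needs subject_id, age, sex, diagnosis.
    """
    sub = summaries[summaries["metric"] == spec.metric_name]
    merged = sub.merge(metadata, on="subject_id", how="inner")
    stratum = merged[merged["sex"] == spec.sex]
    g1 = stratum[stratum["diagnosis"] == spec.contrast[0]]
    g2 = stratum[stratum["diagnosis"] == spec.contrast[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise DataError(
            f"empty group in stratum sex={spec.sex}: "
            f"{spec.contrast[0]}={len(g1)}, {spec.contrast[1]}={len(g2)}"
        )
    col = "mean_value" if spec.test_type == "mean_based" else "peak_value"
    pooled = pd.concat([g1, g2])
    residuals = regress_out_age(pooled[col].to_numpy(), pooled["age"].to_numpy())
    x = residuals[: len(g1)]
    y = residuals[len(g1):]
    rng = np.random.default_rng(comparison_seed(spec.seed, spec))
    perm = permutation_test(
        x,
        y,
        n_permutations=spec.n_permutations,
        rng=rng,
        exhaustive=spec.exhaustive,
        smooth=spec.smooth_p,
    )
    thr = bonferroni_threshold(spec.family_alpha, spec.family_size)
    return ComparisonResult(spec=spec, permutation=perm, bonferroni_threshold=thr)
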