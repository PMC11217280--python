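"""Permutation tests, chi-square tests, tmax correction and effect sizes.

Firing rates, latencies and decay times routinely violate normality and
homoscedasticity, so group comparisons use permutation nulls of the Welch t
statistic (or the one-way F), with the add-one correction
p = (1 + #{|t*| >= |t|}) / (1 + n_perm) for Monte-Carlo permutations and the
exact tail fraction when the permutation space is enumerated exhaustively.
Post-hoc families are corrected with the tmax (max-statistic) method.
Effect sizes follow the design of each test: phi for 2x2 chi-square tables,
Cramer's V for larger tables, eta-squared for one-way ANOVA, and Cohen's d
(paired or unpaired) for t-type comparisons.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "paired_perm_ttest",
    "perm_ttest_ind",
    "perm_anova",
    "tmax_correct",
    "chi_square",
    "cohens_d",
]

DEFAULT_N_PERM = 10_000


@dataclass
class TestResult:
    statistic: float
    p: float
    effect_size_name: str = ""
    effect_size: float = float("nan")
    n: tuple = ()
    n_perm: int = 0
    seed: int | None = None
    exhaustive: bool = False
    extra: dict = field(default_factory=dict)


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    va = a.var(ddof=1) if na > 1 else 0.0
    vb = b.var(ddof=1) if nb > 1 else 0.0
    denom = math.sqrt(va / na + vb / nb)
    if denom == 0:
        return 0.0
    return (a.mean() - b.mean()) / denom


def _paired_t(d: np.ndarray) -> float:
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0 if np.allclose(d, 0) else math.inf * np.sign(d.mean())
    return d.mean() / (sd / math.sqrt(len(d)))


def paired_perm_ttest(
    a,
    b,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    sided: str = "two",
) -> TestResult:
    """Paired permutation t-test by sign-flipping the paired differences.

    Exhaustive (all 2^n sign patterns) whenever 2^n <= n_perm, otherwise
    n_perm random sign flips with the add-one correction.  All-zero
    differences give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length samples with n >= 2")
    d = a - b
    n = len(d)
    if np.allclose(d, 0):
        return TestResult(statistic=0.0, p=1.0, effect_size_name="cohens_d_paired",
                          effect_size=0.0, n=(n,), n_perm=0)
    t_obs = _paired_t(d)

    exhaustive = 2**n <= n_perm
    if exhaustive:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        n_used = len(signs)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_perm, n))
        n_used = n_perm

    flipped = signs * d
    means = flipped.mean(axis=1)
    sds = flipped.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        # zero-SD patterns with a non-zero mean are infinitely extreme
        t_null = np.where(
            sds > 0,
            means / np.where(sds > 0, sds, 1.0) * math.sqrt(n),
            np.sign(means) * np.inf,
        )
        t_null = np.where((sds == 0) & (means == 0), 0.0, t_null)
    if sided == "two":
        hits = np.abs(t_null) >= abs(t_obs) - 1e-12
    elif sided == "greater":
        hits = t_null >= t_obs - 1e-12
    elif sided == "less":
        hits = t_null <= t_obs + 1e-12
    else:
        raise ValueError("sided must be 'two', 'greater' or 'less'")
    if exhaustive:
        p = hits.sum() / n_used
    else:
        p = (1 + hits.sum()) / (1 + n_used)
    return TestResult(
        statistic=float(t_obs), p=float(p),
        effect_size_name="cohens_d_paired", effect_size=cohens_d(a, b, paired=True),
        n=(n,), n_perm=n_used, seed=seed, exhaustive=exhaustive,
    )


def perm_ttest_ind(
    a,
    b,
    n_perm: int = DEFAULT_N_PERM,
    sided: str = "two",
    seed: int | None = None,
) -> TestResult:
    """Permutation t-test for two independent samples (Welch statistic).

    The null permutes group labels; exhaustive over all C(na+nb, na) splits
    when that count does not exceed n_perm.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    na = len(a)
    pooled = np.concatenate([a, b])
    n = len(pooled)
    t_obs = _welch_t(a, b)
    if np.allclose(pooled, pooled[0]):
        return TestResult(statistic=0.0, p=1.0, effect_size_name="cohens_d",
                          effect_size=0.0, n=(na, len(b)), n_perm=0)

    n_total = math.comb(n, na)
    exhaustive = n_total <= n_perm
    if exhaustive:
        t_null = np.array([
            _welch_t(pooled[list(idx)], np.delete(pooled, list(idx)))
            for idx in itertools.combinations(range(n), na)
        ])
        n_used = n_total
    else:
        rng = np.random.default_rng(seed)
        perm = np.argsort(rng.random((n_perm, n)), axis=1)
        shuffled = pooled[perm]
        ga, gb = shuffled[:, :na], shuffled[:, na:]
        va = ga.var(axis=1, ddof=1)
        vb = gb.var(axis=1, ddof=1)
        denom = np.sqrt(va / na + vb / (n - na))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_null = np.where(denom > 0, (ga.mean(axis=1) - gb.mean(axis=1)) / denom, 0.0)
        n_used = n_perm

    if sided == "two":
        hits = np.abs(t_null) >= abs(t_obs) - 1e-12
    elif sided == "greater":
        hits = t_null >= t_obs - 1e-12
    elif sided == "less":
        hits = t_null <= t_obs + 1e-12
    else:
        raise ValueError("sided must be 'two', 'greater' or 'less'")
    p = hits.sum() / n_used if exhaustive else (1 + hits.sum()) / (1 + n_used)
    return TestResult(
        statistic=float(t_obs), p=float(p),
        effect_size_name="cohens_d", effect_size=cohens_d(a, b, paired=False),
        n=(na, len(b)), n_perm=n_used, seed=seed, exhaustive=exhaustive,
    )


def _f_stat(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way F and eta-squared."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ss_total = ss_between + ss_within
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    if ss_within == 0:
        f = math.inf if ss_between > 0 else 0.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
    eta2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, eta2


def perm_anova(groups, n_perm: int = DEFAULT_N_PERM, seed: int | None = None) -> TestResult:
    """One-way permutation ANOVA (label permutation null of the F statistic)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    f_obs, eta2 = _f_stat(groups)
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    cuts = np.cumsum(sizes)[:-1]
    if np.allclose(pooled, pooled[0]):
        return TestResult(statistic=0.0, p=1.0, effect_size_name="eta_squared",
                          effect_size=0.0, n=tuple(sizes), n_perm=0)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        shuffled = rng.permutation(pooled)
        f_star, _ = _f_stat(np.split(shuffled, cuts))
        if f_star >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return TestResult(
        statistic=float(f_obs), p=float(p),
        effect_size_name="eta_squared", effect_size=float(eta2),
        n=tuple(sizes), n_perm=n_perm, seed=seed,
    )


def tmax_correct(
    comparisons,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> list[TestResult]:
    """Family-wise tmax correction for a family of two-sample comparisons.

    ``comparisons`` is a list of (a, b) sample pairs.  For each of n_perm
    joint permutations, every comparison's labels are permuted and the
    maximum |Welch t| across the family is recorded; the adjusted p of
    comparison i is (1 + #{max|t*| >= |t_i|}) / (1 + n_perm).  Adjusted
    p-values dominate the single-comparison permutation p by construction.
    """
    pairs = [(np.asarray(a, float), np.asarray(b, float)) for a, b in comparisons]
    if not pairs:
        raise ValueError("need at least one comparison")
    rng = np.random.default_rng(seed)
    t_obs = np.array([_welch_t(a, b) for a, b in pairs])
    tmax_null = np.zeros(n_perm)
    for k, (a, b) in enumerate(pairs):
        pooled = np.concatenate([a, b])
        na, n = len(a), len(a) + len(b)
        perm = np.argsort(rng.random((n_perm, n)), axis=1)
        shuffled = pooled[perm]
        ga, gb = shuffled[:, :na], shuffled[:, na:]
        va = ga.var(axis=1, ddof=1) if na > 1 else np.zeros(n_perm)
        vb = gb.var(axis=1, ddof=1) if n - na > 1 else np.zeros(n_perm)
        denom = np.sqrt(va / na + vb / (n - na))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_star = np.where(denom > 0, (ga.mean(axis=1) - gb.mean(axis=1)) / denom, 0.0)
        tmax_null = np.maximum(tmax_null, np.abs(t_star))
    out = []
    for k, (a, b) in enumerate(pairs):
        hits = int(np.sum(tmax_null >= abs(t_obs[k]) - 1e-12))
        p_adj = (1 + hits) / (1 + n_perm)
        out.append(
            TestResult(
                statistic=float(t_obs[k]), p=float(p_adj),
                effect_size_name="cohens_d", effect_size=cohens_d(a, b, paired=False),
                n=(len(a), len(b)), n_perm=n_perm, seed=seed,
                extra={"adjusted": True},
            )
        )
    return out


def chi_square(table) -> TestResult:
    """Pearson chi-square on a contingency table (no continuity correction).

    Effect size is phi for 2x2 tables and Cramer's V otherwise.
    """
    table = np.asarray(table)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.number):
        raise ValueError("table must be non-negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has a zero marginal")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    n = table.sum()
    r, c = table.shape
    if (r, c) == (2, 2):
        es_name, es = "phi", math.sqrt(chi2 / n)
    else:
        es_name, es = "cramers_v", math.sqrt(chi2 / (n * (min(r, c) - 1)))
    return TestResult(statistic=float(chi2), p=float(p), effect_size_name=es_name,
                      effect_size=float(es), n=(int(n),), extra={"dof": int(dof)})


def cohens_d(a, b, paired: bool = False) -> float:
    """Cohen's d: pooled-SD (unpaired) or SD-of-differences (paired)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired samples must have equal length")
        d = a - b
        sd = d.std(ddof=1)
        if sd == 0:
            return 0.0 if np.allclose(d, 0) else math.inf * np.sign(d.mean())
        return float(d.mean() / sd)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        diff = a.mean() - b.mean()
        return 0.0 if diff == 0 else math.inf * np.sign(diff)
    return float((a.mean() - b.mean()) / math.sqrt(sp2))
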