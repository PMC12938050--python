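"""Generic inferential operations shared across the analyses.

Conventions (documented in every result): the two-sample test is chosen by a
normality screen (one-sample KS against a normal fitted to each group);
rank-sum effect size is the rank-biserial correlation, signed-rank effect is
|Z|/sqrt(n), and Cohen's d uses the pooled SD. Exact rank-test p-values are
used up to n = 25 per group when there are no ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "choose_and_run_two_sample",
    "ks_family_holm",
    "signed_rank_one_sample",
    "count_rate_comparison",
]

EXACT_N_MAX = 25


@dataclass
class TestResult:
    test: str
    statistic: float
    p: float
    effect_size: float
    effect_convention: str
    n: tuple[int, ...]
    sidedness: str = "two-sided"
    adjustment: str | None = None
    warning: str | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _normality_rejected(x: np.ndarray, alpha: float = 0.05) -> bool:
    """One-sample KS against a normal fitted to the data (location/scale)."""
    x = np.asarray(x, dtype=float)
    if x.std(ddof=1) == 0:
        return True  # constant data: treat as non-normal
    return sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).pvalue < alpha


def _rank_sum(a: np.ndarray, b: np.ndarray, alternative: str, warning: str | None) -> TestResult:
    use_exact = (
        len(a) <= EXACT_N_MAX
        and len(b) <= EXACT_N_MAX
        and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    )
    res = sps.mannwhitneyu(a, b, alternative=alternative, method="exact" if use_exact else "asymptotic")
    u = float(res.statistic)
    r_rb = 1.0 - 2.0 * u / (len(a) * len(b))  # rank-biserial in [-1, 1]
    return TestResult(
        test="wilcoxon-rank-sum",
        statistic=u,
        p=float(res.pvalue),
        effect_size=float(r_rb),
        effect_convention="rank-biserial r",
        n=(len(a), len(b)),
        sidedness=alternative,
        warning=warning,
    )


def choose_and_run_two_sample(
    a, b, alternative: str = "two-sided", force: str | None = None
) -> TestResult:
    """Normality-screened two-sample comparison.

    If either group rejects normality at 0.05 (KS vs fitted normal), a
    Wilcoxon rank-sum test with rank-biserial r is run; otherwise Welch's t
    with Cohen's d (pooled SD). ``force`` in {"ranksum", "welch"} overrides
    the automatic choice. Constant groups fall back to the rank-sum path with
    a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")
    warning = None
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        warning = "constant group; rank-sum used"
        choice = "ranksum"
    elif force is not None:
        choice = force
    else:
        choice = "ranksum" if (_normality_rejected(a) or _normality_rejected(b)) else "welch"

    if choice == "ranksum":
        return _rank_sum(a, b, alternative, warning)
    if choice != "welch":
        raise ValueError("force must be 'ranksum' or 'welch'")
    res = sps.ttest_ind(a, b, equal_var=False, alternative=alternative)
    na, nb = len(a), len(b)
    pooled_sd = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    d = (a.mean() - b.mean()) / pooled_sd if pooled_sd > 0 else np.nan
    return TestResult(
        test="welch-t",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        effect_size=float(d),
        effect_convention="cohen-d (pooled SD)",
        n=(na, nb),
        sidedness=alternative,
    )


def ks_family_holm(sample_pairs: list[tuple]) -> list[TestResult]:
    """Two-sample KS per pair with Holm step-down adjusted p-values."""
    if not sample_pairs:
        raise ValueError("at least one pair required")
    raw = []
    for a, b in sample_pairs:
        res = sps.ks_2samp(np.asarray(a, float), np.asarray(b, float))
        raw.append((float(res.statistic), float(res.pvalue), (len(a), len(b))))
    _, p_adj, _, _ = multipletests([p for _, p, _ in raw], method="holm")
    return [
        TestResult(
            test="ks-2samp",
            statistic=d,
            p=float(pa),
            effect_size=d,
            effect_convention="KS D",
            n=n,
            adjustment="holm",
        )
        for (d, _, n), pa in zip(raw, p_adj)
    ]


def signed_rank_one_sample(x, mu0: float, alternative: str = "two-sided") -> TestResult:
    """One-sample Wilcoxon signed-rank test against the null median ``mu0``.

    The statistic V is the sum of ranks of positive differences (exact p for
    n <= 25 without ties; normal approximation with tie correction
    otherwise). Exact ties with mu0 are dropped and reported; effect size is
    |Z|/sqrt(n).
    """
    x = np.asarray(x, dtype=float)
    d = x - mu0
    n_dropped = int((d == 0).sum())
    d = d[d != 0]
    n = len(d)
    if n < 3:
        raise ValueError("fewer than 3 nonzero differences")
    ranks = sps.rankdata(np.abs(d))
    V = float(ranks[d > 0].sum())

    has_ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= EXACT_N_MAX and not has_ties) else "approx"
    res = sps.wilcoxon(d, alternative=alternative, method=method, correction=False)
    p = float(res.pvalue)
    # |Z| from the normal approximation of V (tie-corrected), for the effect size
    mean_v = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum() / 48.0
    sd_v = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    z = (V - mean_v) / sd_v if sd_v > 0 else np.nan
    return TestResult(
        test="wilcoxon-signed-rank",
        statistic=V,
        p=p,
        effect_size=float(abs(z) / np.sqrt(n)),
        effect_convention="r = |Z|/sqrt(n)",
        n=(n,),
        sidedness=alternative,
        warning=f"{n_dropped} exact ties with mu0 dropped" if n_dropped else None,
    )


def count_rate_comparison(counts, condition_labels) -> dict:
    """Poisson (log-link) regression of event counts on a binary condition.

    Returns the log rate ratio for the non-reference condition with SE, z and
    p. The reference level is the first label in sorted order. An all-zero
    reference group is reported non-estimable rather than silently offset.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise ValueError("counts must be nonnegative integers")
    labels = pd.Series(condition_labels)
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError("exactly two condition levels required")
    ref, alt = levels
    if counts[labels == ref].sum() == 0:
        return {"estimable": False, "reason": f"all-zero reference group {ref!r}"}
    X = sm.add_constant((labels == alt).astype(float).to_numpy())
    fit = sm.GLM(counts, X, family=sm.families.Poisson()).fit()
    return {
        "estimable": True,
        "reference": ref,
        "condition": alt,
        "log_rate_ratio": float(fit.params[1]),
        "se": float(fit.bse[1]),
        "z": float(fit.tvalues[1]),
        "p": float(fit.pvalues[1]),
    }
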