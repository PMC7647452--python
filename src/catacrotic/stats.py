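"""Nonparametric statistics for the stimulus-response study.

The centerpiece is the prediction probability P_K, a concordance measure
between an ordinal predictor (here the analgesic target concentration)
and a continuous response (a post-stimulus parameter value).  Over all
subject pairs with different predictor levels, with C concordant pairs,
D discordant pairs and T response-tied pairs,

    pk_raw = (C + T/2) / (C + D + T)

which equals (Somers' d_yx + 1)/2.  Because a parameter may move with or
against the concentration, the reported value is
``pk = max(pk_raw, 1 - pk_raw)`` with a direction flag, and the standard
error comes from a delete-one-subject jackknife of ``pk_raw``.

Around it: Wilcoxon signed-rank (exact sign-flip distribution up to
n = 25, with average ranks under ties), Mann-Whitney, Kruskal-Wallis,
a Spearman correlation matrix, and a two-group sample-size computation
by noncentral-t power iteration.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

__all__ = [
    "PKResult",
    "TestResult",
    "PredictionProbability",
    "pk_statistic",
    "wilcoxon_signed_rank",
    "mann_whitney",
    "kruskal_wallis",
    "spearman_matrix",
    "sample_size_two_groups",
    "analyze_study",
]

#: largest n for which the signed-rank null distribution is enumerated
WILCOXON_EXACT_MAX_N = 25
#: largest group size for which the Mann-Whitney p is exact (no ties)
MANNWHITNEY_EXACT_MAX_N = 20


@dataclass
class PKResult:
    """Prediction probability with jackknife standard error."""

    pk: float
    pk_raw: float
    se: float
    n: int
    direction: str  # "concordant" or "anticoncordant"
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "pk": self.pk, "pk_raw": self.pk_raw, "se": self.se,
            "n": self.n, "direction": self.direction, "n_pairs": self.n_pairs,
        }


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    labels: tuple = ()
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "test": self.name, "statistic": self.statistic, "p_value": self.p_value,
            "n": list(self.n), "labels": list(self.labels), "note": self.note,
        }


# ---------------------------------------------------------------------------
# prediction probability

def _pk_raw(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """(C + T/2)/(C + D + T) over pairs with distinct x, and the pair count."""
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(x.size, k=1)
    dx, dy = dx[iu], dy[iu]
    keep = dx != 0
    dx, dy = dx[keep], dy[keep]
    total = dx.size
    if total == 0:
        raise ValueError("prediction probability undefined: all predictor values tied")
    conc = int(np.sum(dx * dy > 0))
    ties = int(np.sum(dy == 0))
    return (conc + ties / 2.0) / total, total


def pk_statistic(x, y) -> PKResult:
    """Prediction probability of ``y`` ordering pairs by the ordinal ``x``.

    Requires at least two distinct predictor levels and no missing
    responses.  ``pk`` is reported on the same-or-opposite-direction
    convention (always >= 0.5) with the raw value alongside.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if np.unique(x).size < 2:
        raise ValueError("prediction probability needs >= 2 distinct predictor levels")
    if np.any(np.isnan(y)) or np.any(np.isnan(x)):
        raise ValueError("missing values are not allowed")

    raw, n_pairs = _pk_raw(x, y)

    # delete-one-subject jackknife; replicates that lose the second
    # predictor level are skipped
    reps = []
    for i in range(x.size):
        xi = np.delete(x, i)
        if np.unique(xi).size < 2:
            continue
        reps.append(_pk_raw(xi, np.delete(y, i))[0])
    if len(reps) >= 2:
        reps = np.asarray(reps)
        m = len(reps)
        se = float(np.sqrt((m - 1) / m * np.sum((reps - reps.mean()) ** 2)))
    else:
        se = float("nan")

    direction = "concordant" if raw >= 0.5 else "anticoncordant"
    return PKResult(
        pk=float(max(raw, 1.0 - raw)),
        pk_raw=float(raw),
        se=se,
        n=int(x.size),
        direction=direction,
        n_pairs=n_pairs,
    )


class PredictionProbability(BaseEstimator):
    """P_K concordance estimator with a scikit-learn surface.

    ``fit(x, y)`` computes the statistic; results land in the trailing-
    underscore attributes ``pk_``, ``pk_raw_``, ``se_``, ``direction_``.
    """

    def fit(self, X, y):
        res = pk_statistic(X, y)
        self.pk_ = res.pk
        self.pk_raw_ = res.pk_raw
        self.se_ = res.se
        self.direction_ = res.direction
        self.n_ = res.n
        self.result_ = res
        return self


# ---------------------------------------------------------------------------
# rank tests

def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank statistic by sign-flip
    enumeration, via an integer DP over doubled (average) ranks."""
    r2 = np.rint(2 * ranks).astype(np.int64)  # average ranks are half-integers
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[:-r or None].copy() if r else counts.copy()
    counts /= 2.0 ** len(r2)
    w2 = int(round(2 * w_plus))
    p_low = counts[: w2 + 1].sum()
    p_high = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def wilcoxon_signed_rank(pre, post) -> TestResult:
    """Paired two-sided Wilcoxon signed-rank test of post against pre.

    Zero differences are dropped; with none left the result is p = 1 with
    a warning.  Exact sign-flip distribution (average ranks under ties)
    up to n = 25 remaining pairs, tie-corrected normal approximation
    beyond.
    """
    pre = np.asarray(pre, dtype=float).ravel()
    post = np.asarray(post, dtype=float).ravel()
    if pre.size != post.size:
        raise ValueError("pre and post must be paired (equal length)")
    d = post - pre
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return TestResult("wilcoxon", 0.0, 1.0, (pre.size,), note="all differences zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if d.size <= WILCOXON_EXACT_MAX_N:
        p = _signed_rank_exact_p(ranks, w_plus)
        note = "exact"
    else:
        p = float(sps.wilcoxon(d, method="approx", correction=True).pvalue)
        note = "normal approximation"
    return TestResult("wilcoxon", w_plus, p, (int(d.size),), note=note)


def mann_whitney(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test between two independent groups.

    Exact for small groups without ties, tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and max(a.size, b.size) <= MANNWHITNEY_EXACT_MAX_N:
        method, note = "exact", "exact"
    else:
        method, note = "asymptotic", "normal approximation"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        "mann-whitney", float(res.statistic), float(res.pvalue),
        (int(a.size), int(b.size)), note=note,
    )


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected, chi-square p on k-1 df)."""
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    sizes = tuple(len(g) for g in groups)
    if any(s < 2 for s in sizes):
        raise ValueError("each group needs n >= 2")
    res = sps.kruskal(*groups)
    return TestResult("kruskal-wallis", float(res.statistic), float(res.pvalue), sizes)


def spearman_matrix(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho (average ranks) and t-approximation p values.

    ``values``: subjects x parameters.  Constant columns give NaN entries
    for their pairs.
    """
    cols = list(values.columns)
    if len(values) < 5:
        raise ValueError("need >= 5 subjects for the correlation matrix")
    k = len(cols)
    rho = np.ones((k, k))
    p = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        xi = values.iloc[:, i].to_numpy(dtype=float)
        xj = values.iloc[:, j].to_numpy(dtype=float)
        if np.all(xi == xi[0]) or np.all(xj == xj[0]):
            r, pv = float("nan"), float("nan")
        else:
            res = sps.spearmanr(xi, xj)
            r, pv = float(res.statistic), float(res.pvalue)
        rho[i, j] = rho[j, i] = r
        p[i, j] = p[j, i] = pv
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def sample_size_two_groups(diff: float, sd: float, alpha: float = 0.05,
                           power: float = 0.8) -> int:
    """Smallest per-group n for a two-sample two-tailed t test to detect a
    mean difference ``diff`` with common SD ``sd`` at the requested alpha
    and power, by iterating n upward over the noncentral t distribution
    (noncentrality ``(diff/sd) sqrt(n/2)``, ``2n - 2`` df)."""
    if diff <= 0 or sd <= 0:
        raise ValueError("diff and sd must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    d = diff / sd
    for n in range(2, 1_000_001):
        df = 2 * n - 2
        nc = d * np.sqrt(n / 2.0)
        tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
        achieved = sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc)
        if achieved >= power:
            return n
    raise RuntimeError("no feasible sample size below 1e6")


# ---------------------------------------------------------------------------
# study-level battery

def analyze_study(frame: pd.DataFrame,
                  alpha: float = 0.05,
                  sample_size_spec: tuple[float, float, float, float] = (0.1, 0.08, 0.05, 0.8),
                  ) -> dict:
    """Run the full statistical battery on a study frame.

    ``frame``: long-form table with columns ``subject``, ``ce``,
    ``parameter``, ``pre_value``, ``post_value`` (one row per subject and
    parameter).  Produces, per parameter: within-group Wilcoxon pre vs
    post, pairwise between-group Mann-Whitney on post-values, the Spearman
    matrix of post-values, and P_K of post-values against the
    concentration.  No multiple-testing correction is applied; the report
    carries the number of tests performed.
    """
    required = {"subject", "ce", "parameter", "pre_value", "post_value"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"study frame lacks columns: {sorted(missing)}")
    groups = np.sort(frame["ce"].unique())
    params = [p for p in frame["parameter"].unique()]
    notices: list[str] = []
    n_tests = 0

    post_wide = frame.pivot_table(index=["subject", "ce"], columns="parameter",
                                  values="post_value")[params]

    report: dict = {
        "groups": [float(g) for g in groups],
        "parameters": list(params),
        "alpha": alpha,
        "n_subjects": int(frame["subject"].nunique()),
    }

    # correlation between post-values of parameters
    if len(post_wide) >= 5:
        rho, pmat = spearman_matrix(post_wide.reset_index(drop=True))
        n_tests += len(params) * (len(params) - 1) // 2
        report["correlation"] = {
            "rho": rho.to_dict(), "p": pmat.to_dict(),
        }
    else:
        notices.append("too few subjects for the correlation matrix")

    # within-group stimulus response: pre vs post per parameter and group
    within: dict = {}
    for par in params:
        within[par] = {}
        sub = frame[frame["parameter"] == par]
        for g in groups:
            gg = sub[sub["ce"] == g]
            res = wilcoxon_signed_rank(gg["pre_value"], gg["post_value"])
            n_tests += 1
            within[par][float(g)] = res.to_dict() | {"significant": res.p_value < alpha}
    report["within_group"] = within

    # between-group discrimination on post-values
    between: dict = {}
    if len(groups) >= 2:
        for par in params:
            between[par] = {}
            sub = frame[frame["parameter"] == par]
            for g1, g2 in itertools.combinations(groups, 2):
                res = mann_whitney(
                    sub.loc[sub["ce"] == g1, "post_value"],
                    sub.loc[sub["ce"] == g2, "post_value"],
                )
                res.labels = (float(g1), float(g2))
                n_tests += 1
                between[par][f"{g1}-{g2}"] = res.to_dict() | {"significant": res.p_value < alpha}
    else:
        notices.append("single group: between-group tests skipped")
    report["between_group"] = between

    # prediction probability of post-values against concentration
    pk: dict = {}
    if len(groups) >= 2:
        for par in params:
            sub = frame[frame["parameter"] == par]
            pk[par] = pk_statistic(sub["ce"], sub["post_value"]).to_dict()
    else:
        notices.append("single group: prediction probability skipped")
    report["prediction_probability"] = pk

    diff, sd, a, pw = sample_size_spec
    report["sample_size"] = {
        "diff": diff, "sd": sd, "alpha": a, "power": pw,
        "n_per_group": sample_size_two_groups(diff, sd, a, pw),
    }
    report["n_tests"] = n_tests
    report["notices"] = notices
    return report
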