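"""Group-level behavioral statistics.

One-sample t (raw sample or printed summary statistics), balanced
repeated-measures ANOVA with Mauchly sphericity checks and conditional
Greenhouse-Geisser correction, Wilcoxon signed-rank with the tie- and
continuity-corrected normal approximation, and Spearman rank
correlation.  Every test returns a :class:`TestResult`; undefined cases
(zero variance, all-zero differences) are flagged with NaN statistics
rather than raising or silently returning 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
import scipy.stats as st

__all__ = [
    "TestResult",
    "one_sample_t",
    "rm_anova",
    "wilcoxon_signed_rank",
    "spearman",
]


@dataclass
class TestResult:
    name: str
    statistic: float
    df: tuple[float, ...] | float | None
    p_two_tailed: float
    correction: str = "none"            # "none" | "greenhouse_geisser"
    extras: dict = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return not (isinstance(self.statistic, float)
                    and math.isnan(self.statistic))


def _undefined(name: str, reason: str, df=None) -> TestResult:
    return TestResult(name=name, statistic=float("nan"), df=df,
                      p_two_tailed=float("nan"),
                      extras={"undefined": reason})


def one_sample_t(sample=None, *, mean: float | None = None,
                 sd: float | None = None, n: int | None = None,
                 mu: float = 0.0) -> TestResult:
    """Two-tailed one-sample t test against ``mu``.

    Accepts either a raw sample or printed summary statistics
    ``(mean, sd, n)``; both entry points evaluate the same
    ``t = (mean - mu) / (sd / sqrt(n))`` with ``df = n - 1``.
    """
    if sample is not None:
        x = np.asarray(sample, dtype=float)
        n = x.size
        mean = float(x.mean())
        sd = float(x.std(ddof=1))
    if mean is None or sd is None or n is None:
        raise ValueError("provide a sample or (mean, sd, n)")
    if n < 2:
        raise ValueError("need n >= 2")
    if sd <= 0:
        return _undefined("one_sample_t", "zero standard deviation", df=n - 1)
    t = (mean - mu) / (sd / math.sqrt(n))
    p = 2 * st.t.sf(abs(t), n - 1)
    return TestResult(name="one_sample_t", statistic=t, df=float(n - 1),
                      p_two_tailed=float(p),
                      extras={"mean": mean, "sd": sd, "n": n, "mu": mu})


def _cells_to_long(cells: np.ndarray) -> tuple[pd.DataFrame, list[str]]:
    """(subject, A[, B]) cell array -> long data frame."""
    cells = np.asarray(cells, dtype=float)
    if cells.ndim == 2:
        cells = cells[:, :, None]
    if cells.ndim != 3:
        raise ValueError("cells must be subject x factorA [x factorB]")
    if np.isnan(cells).any():
        raise ValueError("missing cells: the design must be complete")
    n_s, n_a, n_b = cells.shape
    subj, a, b = np.meshgrid(np.arange(n_s), np.arange(n_a),
                             np.arange(n_b), indexing="ij")
    df = pd.DataFrame({"subject": subj.ravel(), "A": a.ravel(),
                       "B": b.ravel(), "y": cells.ravel()})
    factors = ["A"] if n_b == 1 else ["A", "B"]
    return df, factors


def _mauchly(df: pd.DataFrame, factor: str, other: str | None):
    """Mauchly test of sphericity for one within factor (collapsing the
    other factor by its subject mean first)."""
    data = df
    if other is not None:
        data = (df.groupby(["subject", factor], as_index=False)["y"].mean())
    res = pg.sphericity(data, dv="y", within=factor, subject="subject")
    return float(res.W), float(res.pval)


def rm_anova(cells, alpha_sphericity: float = 0.05) -> list[TestResult]:
    """Balanced repeated-measures ANOVA on a subject x A (x B) cell array.

    Returns one :class:`TestResult` per effect (main effects and, for
    two factors, the interaction).  For each within factor with more
    than two levels, Mauchly's test is run on the factor's
    subject-by-level means; when it rejects at ``alpha_sphericity`` the
    Greenhouse-Geisser epsilon scales that effect's degrees of freedom
    and the corrected p value is reported.  The interaction is corrected
    whenever either of its factors failed sphericity.
    """
    df, factors = _cells_to_long(cells)
    aov = pg.rm_anova(data=df, dv="y", within=factors, subject="subject",
                      correction=True, detailed=True)
    aov.columns = [c.replace("-", "_") for c in aov.columns]
    error_df = None
    if "ddof1" not in aov.columns:        # one-way layout: DF + Error row
        error_df = float(aov.loc[aov["Source"] == "Error", "DF"].iloc[0])
    aov = aov.set_index("Source")

    violated: dict[str, tuple[float, float]] = {}
    for f in factors:
        if df[f].nunique() > 2:
            other = [o for o in factors if o != f]
            violated[f] = _mauchly(df, f, other[0] if other else None)

    results = []
    for source in aov.index:
        if source in ("Error", "Residual") or source.startswith("Error"):
            continue
        row = aov.loc[source]
        involved = [f for f in factors if f in source.split(" * ")] \
            if " * " in source else [source]
        sphericity_failed = any(
            f in violated and violated[f][1] < alpha_sphericity
            for f in involved)
        eps = float(row["eps"]) if "eps" in row and np.isfinite(row["eps"]) \
            else 1.0
        if "ddof1" in row:
            df1, df2 = float(row["ddof1"]), float(row["ddof2"])
        else:
            df1, df2 = float(row["DF"]), error_df
        if sphericity_failed and eps < 1.0:
            p = float(row["p_GG_corr"])
            res = TestResult(
                name=f"rm_anova[{source}]", statistic=float(row["F"]),
                df=(df1 * eps, df2 * eps), p_two_tailed=p,
                correction="greenhouse_geisser",
                extras={"eps": eps, "p_uncorrected": float(row["p_unc"])})
        else:
            res = TestResult(
                name=f"rm_anova[{source}]", statistic=float(row["F"]),
                df=(df1, df2), p_two_tailed=float(row["p_unc"]))
        for f in involved:
            if f in violated:
                res.extras[f"mauchly_W[{f}]"] = violated[f][0]
                res.extras[f"mauchly_p[{f}]"] = violated[f][1]
        results.append(res)
    return results


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Paired Wilcoxon signed-rank test, normal approximation.

    Zero differences are dropped; the Z statistic carries tie and
    continuity corrections so its sign reflects the direction of the
    median difference, matching common statistics-package output.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return _undefined("wilcoxon_signed_rank", "all differences are zero")
    n = d.size
    ranks = st.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4
    ties = np.unique(ranks, return_counts=True)[1]
    sigma2 = n * (n + 1) * (2 * n + 1) / 24 - (ties ** 3 - ties).sum() / 48
    num = w_pos - mu
    if num != 0:
        num -= 0.5 * np.sign(num)       # continuity correction
    z = num / math.sqrt(sigma2)
    return TestResult(name="wilcoxon_signed_rank",
                      statistic=float(z), df=None,
                      p_two_tailed=float(2 * st.norm.sf(abs(z))),
                      extras={"W_positive": w_pos, "n_nonzero": int(n)})


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with the two-tailed t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return _undefined("spearman", "constant input")
    rho, p = st.spearmanr(x, y)
    return TestResult(name="spearman", statistic=float(rho),
                      df=float(x.size - 2), p_two_tailed=float(p),
                      extras={"n": int(x.size)})
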