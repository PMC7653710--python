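"""Group-level statistics used throughout the study.

Two-way factorial ANOVA (diet x genotype designs), Mann-Whitney U,
Kruskal-Wallis H, Pearson/Spearman correlation, Fisher's exact test,
printed-proportion arithmetic, the transcriptomic response-concordance
classifier, and relative qPCR expression (2^-ddCt).

Standard tests delegate to statsmodels / scipy; this module fixes the
conventions the analysis relies on (Type II sums of squares, exact
Mann-Whitney p for small tie-free samples, half-up rounding of printed
percentages, the Z-cutoff classification rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FactorialDesign",
    "TestResult",
    "ZRecord",
    "ContingencyTable",
    "two_way_anova",
    "mann_whitney",
    "kruskal_wallis",
    "correlation",
    "fisher_exact",
    "proportion",
    "classify_response",
    "ddct_fold_change",
    "benjamini_hochberg",
    "round_half_up",
]


@dataclass
class FactorialDesign:
    """Responses with two crossed between-subject factors."""

    response: np.ndarray
    factor_a: np.ndarray
    factor_b: np.ndarray
    subject: np.ndarray | None = None

    def __post_init__(self):
        self.response = np.asarray(self.response, dtype=float)
        self.factor_a = np.asarray(self.factor_a)
        self.factor_b = np.asarray(self.factor_b)
        if not (len(self.response) == len(self.factor_a) == len(self.factor_b)):
            raise ValueError("response and factor vectors must have equal length")
        for name, f in (("A", self.factor_a), ("B", self.factor_b)):
            if len(np.unique(f)) < 2:
                raise ValueError(f"factor {name} must have at least 2 levels")


@dataclass
class TestResult:
    """A named test statistic with its p-value and optional df/effect info."""

    name: str
    statistic: float
    p_value: float
    df: tuple | None = None
    extras: dict = field(default_factory=dict)


@dataclass
class ZRecord:
    """Per-gene Z statistics for two contrasts and the assigned class."""

    gene: str
    z1: float
    z2: float
    category: str = ""


@dataclass
class ContingencyTable:
    """2x2 (or r x c) table of non-negative integer counts."""

    counts: np.ndarray
    row_labels: tuple = ()
    col_labels: tuple = ()

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("contingency counts must be non-negative")


def two_way_anova(design: FactorialDesign) -> dict[str, TestResult]:
    """Two-way between-subject ANOVA with interaction.

    Uses Type II sums of squares (identical to Type I/III for balanced
    designs).  Returns ``TestResult`` objects keyed ``"A"``, ``"B"`` and
    ``"A:B"`` with F statistics, (df_effect, df_error) and p-values.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {"y": design.response, "A": design.factor_a.astype(str), "B": design.factor_b.astype(str)}
    )
    cells = df.groupby(["A", "B"], observed=True).size()
    n_a = df["A"].nunique()
    n_b = df["B"].nunique()
    if len(cells) < n_a * n_b or (cells < 1).any():
        raise ValueError("every factor-level cell must be nonempty to estimate the interaction")
    df_error = len(df) - n_a * n_b
    if df_error <= 0:
        raise ValueError(
            "zero error degrees of freedom: at least one cell needs >= 2 observations"
        )
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = {}
    mapping = {"C(A)": "A", "C(B)": "B", "C(A):C(B)": "A:B"}
    dfe = float(table.loc["Residual", "df"])
    for row, key in mapping.items():
        f = float(table.loc[row, "F"])
        # all-equal cell means give SS ~ 0 up to rounding; clamp tiny negatives
        if abs(f) < 1e-12:
            f = 0.0
        out[key] = TestResult(
            name="F",
            statistic=f,
            p_value=float(table.loc[row, "PR(>F)"]),
            df=(float(table.loc[row, "df"]), dfe),
            extras={"ss": float(table.loc[row, "sum_sq"])},
        )
    return out


def mann_whitney(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test.

    Exact p by enumeration when ``n1 + n2 <= 14`` and there are no ties,
    otherwise the normal approximation with tie correction (and continuity
    correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(x) + len(y) <= 14) and not has_ties
    res = sps.mannwhitneyu(x, y, alternative=alternative, method="exact" if exact else "asymptotic")
    return TestResult(
        name="U",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        extras={"method": "exact" if exact else "normal_approx", "n": (len(x), len(y))},
    )


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal-Wallis H test with tie correction.

    All-identical data yields H = 0, p = 1 (no evidence of any difference).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("all groups must be nonempty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(name="H", statistic=0.0, p_value=1.0, df=(len(arrays) - 1,))
    res = sps.kruskal(*arrays)
    return TestResult(
        name="H",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=(len(arrays) - 1,),
    )


def correlation(x, y, method: str = "pearson") -> TestResult:
    """Pearson r or Spearman rho with t-approximation p-value.

    Zero-variance input yields a NaN coefficient with a warning rather
    than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance in correlation input; coefficient undefined")
        return TestResult(name={"pearson": "r", "spearman": "rho"}[method],
                          statistic=float("nan"), p_value=float("nan"),
                          extras={"n": len(x)})
    if method == "pearson":
        res = sps.pearsonr(x, y)
        name = "r"
    elif method == "spearman":
        res = sps.spearmanr(x, y)
        name = "rho"
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return TestResult(name=name, statistic=float(res.statistic),
                      p_value=float(res.pvalue), extras={"n": len(x)})


def fisher_exact(table: ContingencyTable | np.ndarray, alternative: str = "two-sided") -> TestResult:
    """Fisher's exact test on a 2x2 table.

    Conditional (hypergeometric) p-value; the statistic is the sample odds
    ratio ``ad/bc`` (infinite when a zero cell makes it so).
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, dtype=int)
    if counts.shape != (2, 2):
        raise ValueError("fisher_exact requires a 2x2 table")
    if np.any(counts < 0):
        raise ValueError("contingency counts must be non-negative")
    a, b = counts[0]
    c, d = counts[1]
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    res = sps.fisher_exact(counts, alternative=alternative)
    return TestResult(name="OR", statistic=float(odds), p_value=float(res.pvalue),
                      extras={"alternative": alternative})


def round_half_up(value: float, digits: int = 0) -> float:
    """Decimal half-up rounding (the convention of the printed tables)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def proportion(k: int, n: int, digits: int = 0) -> float:
    """Percentage ``100*k/n`` rounded half-up to ``digits`` decimals."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    return round_half_up(100.0 * k / n, digits)


def classify_response(
    records: list[tuple[str, float, float]] | list[ZRecord], cutoff: float = 2.5
) -> tuple[list[ZRecord], TestResult]:
    """Classify per-gene responses across two contrasts and correlate them.

    Rule (applied to the pair of Z statistics ``(z1, z2)`` for the first
    and second contrast):

    * ``concordant``  — both exceed the cutoff in magnitude, same sign;
    * ``discordant``  — ``|z1| > cutoff`` but ``|z2| <= cutoff`` (a
      response present under the first condition, lost under the second);
    * ``enhanced``    — ``|z2| > cutoff`` but ``|z1| <= cutoff``;
    * ``neither``     — anything else.

    The classes partition the records exhaustively and exclusively.  Also
    returns the genome-wide Pearson correlation of ``(z1, z2)``.
    """
    out: list[ZRecord] = []
    for rec in records:
        if isinstance(rec, ZRecord):
            gene, z1, z2 = rec.gene, rec.z1, rec.z2
        else:
            gene, z1, z2 = rec
        if not (np.isfinite(z1) and np.isfinite(z2)):
            raise ValueError(f"non-finite Z for gene {gene!r}")
        if abs(z1) > cutoff and abs(z2) > cutoff and np.sign(z1) == np.sign(z2):
            cat = "concordant"
        elif abs(z1) > cutoff and abs(z2) <= cutoff:
            cat = "discordant"
        elif abs(z2) > cutoff and abs(z1) <= cutoff:
            cat = "enhanced"
        else:
            cat = "neither"
        out.append(ZRecord(gene=gene, z1=float(z1), z2=float(z2), category=cat))
    z1s = np.array([r.z1 for r in out])
    z2s = np.array([r.z2 for r in out])
    if len(out) >= 3:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corr = correlation(z1s, z2s, "pearson")
    else:
        corr = TestResult(name="r", statistic=float("nan"), p_value=float("nan"),
                          extras={"n": len(out)})
    return out, corr


def ddct_fold_change(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by the 2^-ddCt method."""
    for v in (ct_target_sample, ct_ref_sample, ct_target_control, ct_ref_control):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg FDR-adjusted p-values (for transcriptomic tables)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out
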