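"""Cohort-comparison statistics for multi-site patient characteristics.

Pearson chi-square (no continuity correction) for r x c contingency tables,
one-way ANOVA from raw samples or from per-group summary statistics, and
Fisher's exact test (exact for 2 x 2; seeded Monte-Carlo for larger tables).

A reference four-hospital characteristics table (per-site counts of
response, sex, histology, TNM stages, plus age summaries) ships as CSV
fixtures and can be reproduced end to end with
:func:`reference_cohort_report`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "TestResult",
    "chi_square_test",
    "anova_oneway",
    "fisher_exact",
    "fisher_exact_mc",
    "load_reference_tables",
    "load_reference_age_summary",
    "reference_cohort_report",
]


@dataclass
class ContingencyTable:
    """r x c nonnegative integer counts with row/column labels."""

    counts: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("contingency table must be at least 2 x 2")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)) or np.any(self.counts < 0):
                raise ValueError("counts must be nonnegative integers")
            self.counts = self.counts.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if self.counts.sum() == 0:
            raise ValueError("grand total must be positive")
        r, c = self.counts.shape
        self.row_labels = self.row_labels or [f"r{i}" for i in range(r)]
        self.col_labels = self.col_labels or [f"c{j}" for j in range(c)]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str = "") -> "ContingencyTable":
        """Build from a frame whose first column holds row labels."""
        rows = df.iloc[:, 0].astype(str).tolist()
        counts = df.iloc[:, 1:].to_numpy()
        return cls(counts=counts, row_labels=rows, col_labels=list(df.columns[1:]), name=name)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class TestResult:
    statistic: float
    df: tuple[int, ...] | int | None
    p_value: float
    method: str
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def chi_square_test(table: ContingencyTable | np.ndarray) -> TestResult:
    """Pearson chi-square test of independence on an r x c table.

    No continuity correction.  Expected counts E = row * col / total must all
    be positive; any expected count below 5 is flagged (the asymptotic
    approximation is then doubtful and Fisher's exact test may be preferred).
    """
    t = table if isinstance(table, ContingencyTable) else ContingencyTable(np.asarray(table))
    counts = t.counts
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("chi-square test undefined: a row or column marginal is zero")
    res = stats.chi2_contingency(counts, correction=False)
    flags = []
    if np.any(res.expected_freq < 5):
        flags.append("expected count < 5")
    return TestResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        method="Pearson chi-square",
        flags=flags,
    )


def anova_oneway(
    groups: list[np.ndarray] | None = None,
    summaries: list[tuple[float, float, int]] | None = None,
) -> TestResult:
    """One-way ANOVA F-test across k groups.

    Accepts either raw samples (``groups``) or per-group summary statistics
    ``(mean, sd, n)`` with sd the n-1 sample standard deviation; both routes
    use the same between/within sum-of-squares decomposition, so they agree
    exactly when the summaries are computed from the raw data.
    """
    if (groups is None) == (summaries is None):
        raise ValueError("provide exactly one of groups or summaries")
    if groups is not None:
        groups = [np.asarray(g, dtype=float) for g in groups]
        if len(groups) < 2 or any(len(g) < 2 for g in groups):
            raise ValueError("need at least 2 groups with at least 2 values each")
        summaries = [(g.mean(), g.std(ddof=1), len(g)) for g in groups]

    means = np.array([m for m, _, _ in summaries], dtype=float)
    sds = np.array([s for _, s, _ in summaries], dtype=float)
    ns = np.array([n for _, _, n in summaries], dtype=int)
    if len(means) < 2 or np.any(ns < 2):
        raise ValueError("need at least 2 groups with at least 2 values each")

    k, n_total = len(means), int(ns.sum())
    grand = float((ns * means).sum() / n_total)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds ** 2).sum())
    df1, df2 = k - 1, n_total - k

    flags: list[str] = []
    if ss_within == 0.0:
        if ss_between == 0.0:
            raise ValueError("all values identical: F statistic undefined")
        flags.append("zero within-group variance")
        return TestResult(float("inf"), (df1, df2), 0.0, "one-way ANOVA", flags)
    f = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f, df1, df2))
    return TestResult(float(f), (df1, df2), p, "one-way ANOVA", flags)


def fisher_exact(table: ContingencyTable | np.ndarray) -> TestResult:
    """Two-sided Fisher's exact test on a 2 x 2 table.

    The p-value sums the hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed that of the observed
    table.  Larger tables are rejected with a pointer to
    :func:`fisher_exact_mc`.
    """
    t = table if isinstance(table, ContingencyTable) else ContingencyTable(np.asarray(table))
    if t.shape != (2, 2):
        raise ValueError(
            f"fisher_exact handles 2 x 2 tables only (got {t.shape}); "
            "use fisher_exact_mc for larger tables"
        )
    res = stats.fisher_exact(t.counts, alternative="two-sided")
    return TestResult(
        statistic=float(res.statistic),
        df=None,
        p_value=float(res.pvalue),
        method="Fisher exact (2x2)",
    )


def _log_table_prob(counts: np.ndarray) -> float:
    """Log-probability of an r x c table under fixed margins (hypergeometric)."""
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    n = counts.sum()
    return float(
        gammaln(rows + 1).sum()
        + gammaln(cols + 1).sum()
        - gammaln(n + 1)
        - gammaln(counts + 1).sum()
    )


def fisher_exact_mc(
    table: ContingencyTable | np.ndarray, n_mc: int = 20000, seed: int = 0
) -> TestResult:
    """Monte-Carlo Fisher-type exact test for r x c tables.

    Samples tables with the observed margins (Patefield's algorithm via
    ``scipy.stats.random_table``) and estimates P(prob(T) <= prob(observed)).
    Approximate by construction and flagged as such; deterministic given
    ``seed``.
    """
    t = table if isinstance(table, ContingencyTable) else ContingencyTable(np.asarray(table))
    rng = np.random.default_rng(seed)
    obs_lp = _log_table_prob(t.counts)
    dist = stats.random_table(t.counts.sum(axis=1), t.counts.sum(axis=0))
    draws = dist.rvs(n_mc, random_state=rng)
    lps = np.array([_log_table_prob(d) for d in draws])
    hits = int((lps <= obs_lp + 1e-9).sum())
    p = (hits + 1) / (n_mc + 1)  # add-one: observed table counts as a draw
    return TestResult(
        statistic=float("nan"),
        df=None,
        p_value=float(min(p, 1.0)),
        method=f"Fisher exact (Monte-Carlo, {n_mc} draws)",
        flags=["monte-carlo approximation"],
    )


# ---------------------------------------------------------------------------
# reference cohort fixture

_CHARACTERISTICS = [
    "response",
    "gender",
    "histological_type",
    "tumor_stage",
    "node_stage",
    "metastasis",
    "clinical_stage",
]


def _fixture_path():
    return importlib.resources.files("fedcrt") / "data" / "table1"


def load_reference_tables() -> dict[str, ContingencyTable]:
    """Per-site counts of the reference four-hospital cohort (245 patients)."""
    out = {}
    base = _fixture_path()
    for name in _CHARACTERISTICS:
        df = pd.read_csv(base / f"{name}.csv")
        out[name] = ContingencyTable.from_frame(df, name=name)
    return out


def load_reference_age_summary() -> pd.DataFrame:
    """Per-site age summaries (mean, sd, n, min, max)."""
    return pd.read_csv(_fixture_path() / "age_summary.csv")


def reference_cohort_report() -> pd.DataFrame:
    """Recompute the cohort-comparison statistics for the reference tables.

    Chi-square for every categorical characteristic, one-way ANOVA (from the
    printed summaries) for age.  Returns a frame of
    (characteristic, method, statistic, df, p_value, flags).
    """
    rows = []
    for name, table in load_reference_tables().items():
        res = chi_square_test(table)
        rows.append(
            {
                "characteristic": name,
                "method": res.method,
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "flags": "; ".join(res.flags),
            }
        )
    age = load_reference_age_summary()
    res = anova_oneway(summaries=list(zip(age["mean"], age["sd"], age["n"])))
    rows.append(
        {
            "characteristic": "age",
            "method": res.method,
            "statistic": res.statistic,
            "df": res.df,
            "p_value": res.p_value,
            "flags": "; ".join(res.flags),
        }
    )
    return pd.DataFrame(rows)
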