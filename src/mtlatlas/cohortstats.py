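"""Cohort-level classical statistics.

Type-proportion summaries, one- and two-sample proportion z-tests,
group t-tests with Benjamini-Hochberg FDR across the tested columns, and
the inter-hemispheric conformation-type correlation (phi coefficient).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import fdrcorrection
from statsmodels.stats.proportion import proportions_ztest

__all__ = [
    "TypeProportionSummary",
    "StatResult",
    "summarize_types",
    "proportion_test",
    "group_ttests",
    "interhemispheric_type_correlation",
]


@dataclass
class TypeProportionSummary:
    n_hemispheres: int
    n_type1: int
    n_type2: int
    pct_type1: float  # percent, full precision
    pct_type2: float

    def rounded(self, ndigits: int = 2) -> tuple[float, float]:
        """Display percentages with half-up rounding to ``ndigits``."""
        def half_up(x):
            scale = 10**ndigits
            return float(np.floor(x * scale + 0.5) / scale)

        return half_up(self.pct_type1), half_up(self.pct_type2)

    def printed(self, ndigits: int = 2) -> tuple[float, float]:
        """Percentages in the convention of published sulcal-pattern tables:
        the Type-1 percentage truncated to ``ndigits`` decimals and the
        Type-2 percentage as its complement to 100 (so 29/76 hemispheres
        print as 38.15 / 61.85)."""
        scale = 10**ndigits
        p1 = float(np.floor(self.pct_type1 * scale) / scale)
        return p1, float(np.round((100.0 - p1) * scale) / scale)


@dataclass
class StatResult:
    """A named test statistic with its p-value (and FDR-adjusted p, if any)."""

    method: str
    statistic: float
    p_value: float
    comparison: str = ""
    p_adjusted: float | None = None
    rejected: bool | None = None
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "method": self.method,
            "comparison": self.comparison,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
        }
        if self.p_adjusted is not None:
            out["p_adjusted"] = float(self.p_adjusted)
            out["rejected"] = bool(self.rejected)
        out.update(self.extra)
        return out


def summarize_types(cohort: pd.DataFrame) -> TypeProportionSummary:
    """Count Type 1 / Type 2 hemispheres and their percentages."""
    types = np.asarray(cohort["conformation_type"])
    bad = set(np.unique(types)) - {1, 2}
    if bad:
        raise ValueError(f"unknown conformation types present: {sorted(bad)}")
    n = len(types)
    n1 = int(np.sum(types == 1))
    n2 = n - n1
    return TypeProportionSummary(n, n1, n2, 100.0 * n1 / n, 100.0 * n2 / n)


def proportion_test(count: int, nobs: int, reference, variance: str = "sample") -> StatResult:
    """Proportion z-test against a fixed reference or a second sample.

    One-sample (``reference`` a float p0): z = (p_hat - p0) / se with, by
    default, the sample-proportion variance p_hat(1-p_hat)/n; pass
    ``variance='null'`` for the score-test form p0(1-p0)/n.  Two-sample
    (``reference`` a (count, nobs) pair): pooled-proportion variance.
    Two-sided normal p-values throughout.
    """
    if not 0 <= count <= nobs or nobs <= 0:
        raise ValueError("need 0 <= count <= nobs, nobs > 0")
    if np.isscalar(reference):
        p0 = float(reference)
        phat = count / nobs
        if variance == "sample":
            if phat in (0.0, 1.0):
                raise ValueError(
                    "degenerate sample variance (p_hat in {0,1}); "
                    "use variance='null'"
                )
            z, p = proportions_ztest(count, nobs, value=p0)
        elif variance == "null":
            se = np.sqrt(p0 * (1 - p0) / nobs)
            z = (phat - p0) / se
            p = 2 * stats.norm.sf(abs(z))
        else:
            raise ValueError("variance must be 'sample' or 'null'")
        comparison = f"{count}/{nobs} vs p0={p0}"
    else:
        c2, n2 = reference
        z, p = proportions_ztest(
            np.array([count, c2]), np.array([nobs, n2])
        )
        comparison = f"{count}/{nobs} vs {c2}/{n2}"
    return StatResult("proportion_ztest", float(z), float(p), comparison)


def group_ttests(
    table: pd.DataFrame,
    group_col: str,
    value_cols,
    fdr_alpha: float = 0.05,
) -> list[StatResult]:
    """Two-sided pooled-variance t-tests per column, BH-FDR across columns.

    The correction family is exactly the set of columns tested in this call.
    """
    groups = sorted(pd.unique(table[group_col]))
    if len(groups) != 2:
        raise ValueError(f"group column must have exactly 2 levels, got {groups}")
    a = table[table[group_col] == groups[0]]
    b = table[table[group_col] == groups[1]]
    results = []
    for col in value_cols:
        x = np.asarray(a[col], dtype=float)
        y = np.asarray(b[col], dtype=float)
        if len(x) < 2 or len(y) < 2:
            raise ValueError(f"{col}: need >= 2 observations per group")
        if np.var(x) == 0 and np.var(y) == 0:
            if np.mean(x) == np.mean(y):
                t, p = 0.0, 1.0
            else:
                raise ValueError(f"{col}: zero within-group variance in both groups")
        else:
            t, p = stats.ttest_ind(x, y, equal_var=True)
        results.append(
            StatResult(
                "ttest_ind",
                float(t),
                float(p),
                comparison=f"{col}: {group_col}={groups[0]} vs {groups[1]}",
            )
        )
    rej, p_adj = fdrcorrection([r.p_value for r in results], alpha=fdr_alpha)
    for r, pa, rj in zip(results, p_adj, rej):
        r.p_adjusted = float(pa)
        r.rejected = bool(rj)
    return results


def interhemispheric_type_correlation(cohort: pd.DataFrame) -> StatResult:
    """Pearson correlation (phi) of the binary conformation type across
    subjects' left/right hemisphere pairs."""
    wide = cohort.pivot(
        index="subject_id", columns="hemisphere", values="conformation_type"
    )
    if "L" not in wide.columns or "R" not in wide.columns or wide.isna().any().any():
        missing = wide.index[wide.isna().any(axis=1)].tolist() if not wide.empty else []
        raise ValueError(f"subjects missing a hemisphere: {missing}")
    left = (np.asarray(wide["L"]) == 1).astype(float)
    right = (np.asarray(wide["R"]) == 1).astype(float)
    if np.var(left) == 0 and np.var(right) == 0 and np.all(left == right):
        r = 1.0  # perfect concordance with no variance: fully concordant
    else:
        r = float(np.corrcoef(left, right)[0, 1])
    return StatResult(
        "phi", r, float("nan"), comparison="L vs R conformation type",
        extra={"n_subjects": len(wide)},
    )
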