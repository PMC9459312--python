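"""Clinical scoring rules, group demographics comparison, and correlation.

Group comparisons use Welch's unequal-variance t-test (recomputing published
group summaries with Welch reproduces their printed t-values, which a pooled
t does not). The correlation stage is plain Pearson r with the exact
t-distribution p-value; no multiple-testing correction by default, with an
optional Benjamini-Hochberg screen.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import DEFAULT_COVARIATE_PARAMS, SubjectRecord

# Row order follows the standard demographics-table layout
TABLE_VARIABLES = list(DEFAULT_COVARIATE_PARAMS.keys())


def welch_ttest_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's t, Welch-Satterthwaite dof and two-sided p from summaries."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    dof = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return float(t), float(dof), float(p)


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r with the exact two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


def moca_adjust(raw_total: float, education_years: float) -> float:
    """Education adjustment: +1 point when education < 12 years, capped at 30."""
    if not (0 <= raw_total <= 30):
        raise ValueError("MoCA total must lie in [0, 30]")
    adjusted = raw_total + 1 if education_years < 12 else raw_total
    return min(adjusted, 30)


def classify_ahi(ahi: float) -> str:
    """AHI severity band: normal <5, mild 5-<15, moderate 15-<30, severe >=30.

    An AHI of exactly 30 falls between the quoted moderate (<30) and severe
    (>30) bands; it is assigned to severe here.
    """
    if ahi < 0:
        raise ValueError("AHI must be >= 0")
    if ahi < 5:
        return "normal"
    if ahi < 15:
        return "mild"
    if ahi < 30:
        return "moderate"
    return "severe"


def classify_ess(score: float) -> str:
    """ESS daytime-sleepiness band; all cut-offs are strict 'greater than'."""
    if not (0 <= score <= 24):
        raise ValueError("ESS score must lie in [0, 24]")
    if score > 16:
        return "dangerous"
    if score > 11:
        return "excessive"
    if score > 6:
        return "drowsy"
    return "normal"


def demographics_table(
    cohort: list[SubjectRecord] | pd.DataFrame,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Per-variable group comparison (patient vs control), Welch t from raw values."""
    if isinstance(cohort, pd.DataFrame):
        df = cohort
    else:
        from .synthetic import cohort_dataframe

        df = cohort_dataframe(cohort)
    variables = variables or [v for v in TABLE_VARIABLES if v in df.columns]
    pat = df[df["group"] == "patient"]
    ctl = df[df["group"] == "control"]
    if pat.empty or ctl.empty:
        raise ValueError("both groups must be nonempty")
    rows = []
    for var in variables:
        xs, ys = pat[var].to_numpy(float), ctl[var].to_numpy(float)
        if np.isnan(xs).any() or np.isnan(ys).any():
            raise ValueError(f"missing values in {var}")
        if xs.std(ddof=1) == 0 and ys.std(ddof=1) == 0:
            t, dof, p = 0.0, float(len(xs) + len(ys) - 2), 1.0
        else:
            t, dof, p = welch_ttest_from_summary(
                xs.mean(), max(xs.std(ddof=1), 1e-12), len(xs),
                ys.mean(), max(ys.std(ddof=1), 1e-12), len(ys),
            )
        rows.append(
            {
                "variable": var,
                "patient_mean": xs.mean(),
                "patient_sd": xs.std(ddof=1),
                "control_mean": ys.mean(),
                "control_sd": ys.std(ddof=1),
                "t": t,
                "dof": dof,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def correlate_clusters(
    cluster_values: np.ndarray,
    clinical: pd.DataFrame,
    variables: list[str],
    cluster_names: list[str] | None = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """Pearson r between each cluster-mean column and each clinical variable.

    Mirrors the patients-only correlation screen: pass in patient rows only.
    ``fdr`` adds Benjamini-Hochberg adjusted p-values (off by default: the
    screen is reported uncorrected).
    """
    cluster_values = np.atleast_2d(np.asarray(cluster_values, dtype=float))
    if cluster_values.shape[0] != len(clinical):
        raise ValueError("cluster value rows must match clinical rows")
    names = cluster_names or [f"cluster_{j + 1}" for j in range(cluster_values.shape[1])]
    rows = []
    for j, cname in enumerate(names):
        for var in variables:
            r, p = pearson(cluster_values[:, j], clinical[var].to_numpy(float))
            rows.append(
                {"cluster": cname, "variable": var, "r": r, "p": p,
                 "n": len(clinical)}
            )
    out = pd.DataFrame(rows)
    if fdr and len(out):
        out["p_fdr"] = _benjamini_hochberg(out["p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
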