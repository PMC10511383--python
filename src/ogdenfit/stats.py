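"""Region taxonomy and nonparametric cohort statistics.

The 19 anatomical sampling regions are aggregated into nine ``governing``
regions treated as mechanically homogeneous.  Because the fitted material
parameters are not normally distributed (checked with a Shapiro-Wilk gate),
group comparisons use the Kruskal-Wallis H-test with pairwise post hoc
Mann-Whitney U tests under Holm-Bonferroni family-wise error control, and
paired comparisons between parameter sets (first vs third cycle, nu 0.45 vs
0.49) use the Wilcoxon signed-rank test.  The four parameter sets per
specimen are not independent, so every test is run separately per set.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ANATOMICAL_REGIONS",
    "GOVERNING_REGIONS",
    "GOVERNING_MAP",
    "PARAMETER_SETS",
    "StatTestResult",
    "map_governing_region",
    "shapiro_wilk",
    "kruskal_wallis",
    "holm_adjust",
    "pairwise_mann_whitney_holm",
    "wilcoxon_paired",
    "summarize",
    "paired_differences",
]

ALPHA_LEVEL = 0.05

#: anatomical sampling regions (19 codes)
ANATOMICAL_REGIONS = (
    "Am", "CC", "CI", "CR", "FC", "Hi", "M", "MC", "Me", "NC",
    "P", "Pa", "Pu", "TL", "Th", "VC", "WM", "cN", "cWM",
)

#: governing region of each anatomical region
GOVERNING_MAP = {
    "Am": "Am",
    "Pa": "BG", "Pu": "BG", "NC": "BG",
    "Me": "BS", "P": "BS",
    "MC": "C", "VC": "C", "CI": "C", "FC": "C", "TL": "C",
    "cWM": "CB", "cN": "CB",
    "CC": "CC",
    "CR": "CR", "WM": "CR",
    "Hi": "Hi",
    "M": "M", "Th": "M",
}

GOVERNING_REGIONS = ("Am", "BG", "BS", "C", "CB", "CC", "CR", "Hi", "M")

#: the four fitted parameter sets per specimen: (cycle, nu)
PARAMETER_SETS = ((1, 0.45), (1, 0.49), (3, 0.45), (3, 0.49))


@dataclass(frozen=True)
class StatTestResult:
    """Outcome of one statistical test."""

    test: str
    groups: tuple
    statistic: float
    p_raw: float
    p_adjusted: float | None = None
    n: tuple = ()

    @property
    def significant(self) -> bool:
        p = self.p_adjusted if self.p_adjusted is not None else self.p_raw
        return p < ALPHA_LEVEL


def map_governing_region(anatomical: str) -> str:
    """Governing region code of an anatomical region code."""
    try:
        return GOVERNING_MAP[anatomical]
    except KeyError:
        raise KeyError(
            f"unknown anatomical region {anatomical!r}; "
            f"valid codes: {', '.join(ANATOMICAL_REGIONS)}"
        ) from None


def shapiro_wilk(sample, label: str = "") -> StatTestResult:
    """Shapiro-Wilk normality test (gate for the nonparametric pipeline)."""
    x = np.asarray(sample, float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(x) == 0.0:
        raise ValueError("constant sample")
    w, p = sps.shapiro(x)
    return StatTestResult(
        test="shapiro-wilk", groups=(label,), statistic=float(w), p_raw=float(p),
        n=(x.size,),
    )


def kruskal_wallis(samples: dict) -> StatTestResult:
    """Kruskal-Wallis H-test across the given groups (tie-corrected).

    Nonparametric one-way ANOVA analogue; p from the chi-square
    approximation with k-1 degrees of freedom.
    """
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(v, float) for v in samples.values()]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    h, p = sps.kruskal(*arrays)
    return StatTestResult(
        test="kruskal-wallis",
        groups=tuple(samples),
        statistic=float(h),
        p_raw=float(p),
        n=tuple(a.size for a in arrays),
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm-Bonferroni step-down adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def _mannwhitney_raw(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided U test; exact for small tie-free samples, else normal approx."""
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (min(x.size, y.size) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def pairwise_mann_whitney_holm(samples: dict) -> list[StatTestResult]:
    """All pairwise two-sided Mann-Whitney U tests with Holm adjustment."""
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for k, v in samples.items():
        if np.asarray(v).size == 0:
            raise ValueError(f"group {k!r} is empty")
    pairs = list(combinations(sorted(samples), 2))
    stats_, raws, ns = [], [], []
    for a, b in pairs:
        u, p = _mannwhitney_raw(np.asarray(samples[a], float), np.asarray(samples[b], float))
        stats_.append(u)
        raws.append(p)
        ns.append((np.asarray(samples[a]).size, np.asarray(samples[b]).size))
    adj = holm_adjust(raws)
    return [
        StatTestResult(
            test="mann-whitney-u",
            groups=pair,
            statistic=u,
            p_raw=p,
            p_adjusted=float(q),
            n=n,
        )
        for pair, u, p, q, n in zip(pairs, stats_, raws, adj, ns)
    ]


def wilcoxon_paired(differences, min_nonzero: int = 5) -> StatTestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon's original treatment); the exact
    null distribution is used for up to 25 tie-free non-zero differences,
    otherwise the normal approximation with tie and continuity correction.
    """
    d = np.asarray(differences, float)
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    if d.size < min_nonzero:
        raise ValueError(
            f"only {d.size} non-zero differences; need >= {min_nonzero}"
        )
    ties = np.unique(np.abs(d)).size < d.size
    if d.size <= 25 and not ties:
        res = sps.wilcoxon(d, alternative="two-sided", method="exact")
    else:
        res = sps.wilcoxon(
            d, alternative="two-sided", method="approx", correction=True
        )
    return StatTestResult(
        test="wilcoxon-signed-rank",
        groups=(),
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        n=(d.size,),
    )


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------

def summarize(cohort: pd.DataFrame, by: str) -> pd.DataFrame:
    """Group means/stds/counts of mu, alpha and RMSE.

    ``cohort`` has one row per specimen x parameter set with columns
    specimen_id, brain_id, anatomical_region, governing_region, cycle, nu,
    mu, alpha, rmse.  ``by`` is ``"region"`` (governing), ``"brain"`` or
    ``"parameter_set"``.  Groups of size one report std 0 with an n=1 flag.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    key = {
        "region": ["governing_region", "cycle", "nu"],
        "brain": ["brain_id", "cycle", "nu"],
        "parameter_set": ["cycle", "nu"],
    }[by]
    rows = []
    for g, sub in cohort.groupby(key, sort=True):
        row = dict(zip(key, g if isinstance(g, tuple) else (g,)))
        for col in ("mu", "alpha", "rmse"):
            if col not in sub:
                continue
            row[f"{col}_mean"] = sub[col].mean()
            row[f"{col}_std"] = sub[col].std(ddof=1) if len(sub) > 1 else 0.0
        row["n"] = len(sub)
        row["single_observation"] = len(sub) == 1
        rows.append(row)
    return pd.DataFrame(rows)


def paired_differences(
    cohort: pd.DataFrame,
    set_a: tuple[int, float],
    set_b: tuple[int, float],
) -> pd.DataFrame:
    """Per-specimen differences (a - b) of mu, alpha, rmse between two sets.

    Returns the matched table with one row per specimen present in both
    parameter sets; medians of its columns quantify e.g. the preconditioning
    or compressibility effect.
    """
    a = cohort[(cohort["cycle"] == set_a[0]) & (cohort["nu"] == set_a[1])]
    b = cohort[(cohort["cycle"] == set_b[0]) & (cohort["nu"] == set_b[1])]
    merged = a.merge(b, on="specimen_id", suffixes=("_a", "_b"))
    out = pd.DataFrame({"specimen_id": merged["specimen_id"]})
    for col in ("mu", "alpha", "rmse"):
        if f"{col}_a" in merged:
            out[f"d_{col}"] = merged[f"{col}_a"] - merged[f"{col}_b"]
    return out
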