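"""Statistical battery over composition and ROI-score tables.

Continuous composition comparisons run through a normality gate: every group
is Shapiro–Wilk tested at α = 0.05, and groups that fail are re-tested under
log(y) then 1/y transforms, taking the first transform under which all groups
pass; data that pass under no transform are flagged for the rank-based route.
Parametric comparisons use one-way ANOVA with a Tukey HSD post-hoc; ordinal
ROI scores use the tie-corrected Kruskal–Wallis test with Dunn's pairwise
z-tests (Holm-adjusted by default). ROC AUC for ordinal scores lives in
:mod:`patquant.roi_scoring`; linear regression quantifies cross-modality
concordance of lipid composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05  # significance level used throughout


@dataclass
class StatReport:
    """Outcome of one omnibus test and its post-hoc table."""

    test: str
    groups: list[str]
    statistic: float
    p_value: float
    transform: str = "none"  # none | log | reciprocal | rank_based
    posthoc: pd.DataFrame | None = None
    normality: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def to_dict(self) -> dict:
        d = {
            "test": self.test,
            "groups": self.groups,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "transform": self.transform,
            "normality": self.normality,
        }
        if self.posthoc is not None:
            d["posthoc"] = self.posthoc.to_dict(orient="records")
        return d


def regression_r2(x, y) -> tuple[float, float, float, float]:
    """OLS regression of y on x: (slope, intercept, R², slope-test p).

    R² equals the squared Pearson correlation for simple linear regression.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("observations must be finite")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: regression undefined")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue)


_TRANSFORMS = {
    "none": lambda v: v,
    "log": np.log,
    "reciprocal": lambda v: 1.0 / v,
}


def normality_gate(groups: dict[str, np.ndarray], alpha: float = ALPHA) -> dict:
    """Choose the transform under which all groups pass Shapiro–Wilk.

    Transforms are tried in order none → log → reciprocal; log and reciprocal
    are skipped (with a note) for groups containing non-positive values. If no
    transform normalizes every group, the decision flags the rank-based route.
    """
    groups = {k: np.asarray(v, dtype=np.float64) for k, v in groups.items()}
    for name, v in groups.items():
        if v.size < 3:
            raise ValueError(f"group {name!r} has fewer than 3 observations")
    notes: list[str] = []
    results: dict[str, dict[str, float]] = {}
    for tname in ("none", "log", "reciprocal"):
        if tname != "none" and any((v <= 0).any() for v in groups.values()):
            notes.append(f"{tname} transform skipped: non-positive values present")
            continue
        f = _TRANSFORMS[tname]
        pvals = {name: float(sps.shapiro(f(v)).pvalue) for name, v in groups.items()}
        results[tname] = pvals
        if all(p >= alpha for p in pvals.values()):
            return {"transform": tname, "shapiro_p": pvals, "notes": notes}
    return {
        "transform": "rank_based",
        "shapiro_p": results.get("none", {}),
        "notes": notes + ["no transform normalized all groups; use the rank-based route"],
    }


def anova_tukey(groups: dict[str, np.ndarray], alpha: float = ALPHA) -> StatReport:
    """One-way ANOVA with a Tukey HSD post-hoc pairwise table."""
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=np.float64) for n in names]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two observations")
    f_stat, p = sps.f_oneway(*arrays)
    posthoc = None
    if len(arrays) >= 2:
        values = np.concatenate(arrays)
        labels = np.concatenate([[n] * a.size for n, a in zip(names, arrays)])
        tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
        posthoc = pd.DataFrame(
            tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
        )
    return StatReport(
        test="one_way_anova_tukey", groups=names,
        statistic=float(f_stat), p_value=float(p), posthoc=posthoc,
    )


def _dunn_posthoc(
    arrays: list[np.ndarray], names: list[str], adjust: str
) -> pd.DataFrame:
    """Dunn's pairwise z-tests on Kruskal–Wallis pooled ranks.

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j)) with the tie
    correction T = Σ(t³ − t) / (12(N − 1)); two-sided normal p-values with the
    configured family-wise adjustment.
    """
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start : start + a.size].mean())
        sizes.append(a.size)
        start += a.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for i, j in combinations(range(len(arrays)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group1": names[i], "group2": names[j], "z": float(z), "p_raw": float(p)})
    if adjust == "none":
        for r in rows:
            r["p_adj"] = r["p_raw"]
    else:
        method = {"holm": "holm", "bonferroni": "bonferroni"}[adjust]
        adj = multipletests([r["p_raw"] for r in rows], method=method)[1]
        for r, pa in zip(rows, adj):
            r["p_adj"] = float(pa)
    return pd.DataFrame(rows)


def kruskal_dunn(
    groups: dict[str, np.ndarray], adjust: str = "holm"
) -> StatReport:
    """Tie-corrected Kruskal–Wallis omnibus with Dunn's pairwise post-hoc."""
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=np.float64) for n in names]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise ValueError("all observations identical: H statistic undefined")
    h_stat, p = sps.kruskal(*arrays)
    posthoc = _dunn_posthoc(arrays, names, adjust)
    return StatReport(
        test="kruskal_wallis_dunn", groups=names,
        statistic=float(h_stat), p_value=float(p),
        transform="rank_based", posthoc=posthoc,
    )


def compare_composition_groups(
    groups: dict[str, np.ndarray], alpha: float = ALPHA
) -> StatReport:
    """Full parametric route: normality gate, transform, ANOVA + Tukey.

    Falls back to Kruskal–Wallis + Dunn when no transform normalizes every
    group, recording the decision.
    """
    gate = normality_gate(groups, alpha=alpha)
    transform = gate["transform"]
    if transform == "rank_based":
        report = kruskal_dunn(groups)
        report.normality = gate
        return report
    f = _TRANSFORMS[transform]
    transformed = {k: f(np.asarray(v, dtype=np.float64)) for k, v in groups.items()}
    report = anova_tukey(transformed, alpha=alpha)
    report.transform = transform
    report.normality = gate
    return report
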