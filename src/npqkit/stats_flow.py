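"""Assumption-routed group comparisons.

The experimental design compares accessions against a low-tolerance control
accession (inter-accession family) and treatments against the warm control
(intra-accession family). The routing procedure:

1. Shapiro–Wilk on full-model residuals and Brown–Forsythe (median-centred
   Levene) across groups.
2. If either rejects at alpha, attempt a natural-log transform (positive
   data only) and re-check; if assumptions still fail, branch nonparametric.
3. Parametric branch: factorial ANOVA omnibus, then Dunnett many-to-one
   comparisons against the designated control (single contrasts reduce to
   the pooled two-sample t-test exactly).
   Nonparametric branch: Kruskal–Wallis omnibus, then Conover–Iman rank
   comparisons against the control with Benjamini–Hochberg adjustment
   (single contrasts fall back to the Wilcoxon rank-sum test).

Each many-to-one set sharing a control is one correction family, mirroring
the two separately-starred families in the source figures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, InsufficientDataError

__all__ = [
    "GroupedData",
    "StatRoute",
    "check_assumptions",
    "route_and_test",
    "dunnett",
    "conover_iman_bh",
    "bh_adjust",
    "significance_stars",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone in the input)."""
    _, adj, _, _ = multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")
    return adj


@dataclass
class GroupedData:
    """Long-format response values with design factors and control labels."""

    values: np.ndarray
    factors: pd.DataFrame
    control_accession: str = "MsiCR"
    control_treatment: str = "warm"
    accession_col: str = "accession"
    treatment_col: str = "treatment"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.factors = self.factors.reset_index(drop=True)
        if len(self.values) != len(self.factors):
            raise ValueError("values and factors must have equal length")
        if self.n_cells() < 2:
            raise InsufficientDataError("need at least 2 groups to compare")

    def factor_cols(self) -> list[str]:
        return list(self.factors.columns)

    def cell_labels(self) -> pd.Series:
        return self.factors.astype(str).agg("|".join, axis=1)

    def n_cells(self) -> int:
        return self.cell_labels().nunique()

    def to_frame(self) -> pd.DataFrame:
        df = self.factors.copy()
        df["value"] = self.values
        return df


@dataclass
class StatRoute:
    """Record of the assumption checks, chosen branch, and all comparisons."""

    shapiro_p: float
    brown_forsythe_p: float
    transform_applied: str          # "none" | "log"
    branch: str                     # "parametric" | "nonparametric"
    omnibus: dict = field(default_factory=dict)
    comparisons: pd.DataFrame = field(default_factory=pd.DataFrame)
    alpha: float = 0.05


def _cell_residuals(values: np.ndarray, cells: pd.Series) -> np.ndarray:
    """Residuals from the saturated cell-means model (= full factorial fit)."""
    df = pd.DataFrame({"v": values, "c": cells.values})
    return (df["v"] - df.groupby("c")["v"].transform("mean")).to_numpy()


def check_assumptions(d: GroupedData) -> tuple[float, float]:
    """(Shapiro–Wilk p on residuals, Brown–Forsythe p across groups).

    Constant data (zero residual variance) return (nan, nan); callers route
    such data to the nonparametric branch.
    """
    if len(d.values) < 3:
        raise InsufficientDataError("need n >= 3 for assumption checks")
    cells = d.cell_labels()
    resid = _cell_residuals(d.values, cells)
    if np.allclose(resid, resid[0]):
        return (float("nan"), float("nan"))
    shapiro_p = float(sps.shapiro(resid).pvalue)
    groups = [d.values[(cells == c).to_numpy()] for c in cells.unique()]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        return (shapiro_p, float("nan"))
    bf_p = float(sps.levene(*groups, center="median").pvalue)
    return (shapiro_p, bf_p)


def dunnett(
    groups: list[np.ndarray],
    control_index: int,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Two-sided many-to-one comparisons against a control group.

    Returns one row per non-control group: mean-difference estimate, the
    unadjusted two-sample (pooled-variance, N-k df) p-value, and the
    Dunnett-adjusted p from the multivariate-t distribution of the maximum
    |t| (Monte-Carlo integration, seeded via ``rng``). With exactly one
    comparison the adjusted p IS the two-sided pooled t-test p, computed
    analytically so the reduction is exact.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if not 0 <= control_index < len(groups):
        raise IndexError("control_index out of range")
    if len(groups) < 2:
        raise InsufficientDataError("need a control and at least one treatment group")
    control = groups[control_index]
    if len(control) < 2:
        raise InsufficientDataError("control group needs n >= 2")
    others = [g for i, g in enumerate(groups) if i != control_index]
    if any(len(g) < 2 for g in others):
        raise InsufficientDataError("every group needs n >= 2")

    n_total = sum(len(g) for g in groups)
    k = len(groups)
    df_resid = n_total - k
    s2 = sum(np.sum((g - g.mean()) ** 2) for g in groups) / df_resid
    t_stats, raw_p, estimates = [], [], []
    for g in others:
        est = g.mean() - control.mean()
        se = np.sqrt(s2 * (1.0 / len(g) + 1.0 / len(control)))
        t = est / se if se > 0 else 0.0
        t_stats.append(t)
        estimates.append(est)
        raw_p.append(2.0 * sps.t.sf(abs(t), df_resid))

    if len(others) == 1:
        adj_p = list(raw_p)  # single comparison: Dunnett == two-sided t-test
    else:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        res = sps.dunnett(*others, control=control, alternative="two-sided",
                          random_state=rng)
        adj_p = [float(p) for p in res.pvalue]
    # multiplicity adjustment can only increase p
    adj_p = [min(max(a, r), 1.0) for a, r in zip(adj_p, raw_p)]
    return pd.DataFrame({
        "estimate": estimates,
        "statistic": t_stats,
        "raw_p": raw_p,
        "adjusted_p": adj_p,
        "significant": [p < alpha for p in adj_p],
        "method": "dunnett",
    })


def conover_iman_bh(
    groups: list[np.ndarray],
    control_index: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Conover–Iman rank comparisons vs a control, BH-adjusted within family.

    t-statistics use pooled-rank variance shrunk by the Kruskal–Wallis H
    (Conover's 1979 form), referenced to a t distribution on N-k degrees of
    freedom; Benjamini–Hochberg controls the FDR across the many-to-one
    family.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise InsufficientDataError("need a control and at least one treatment group")
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    k = len(groups)
    if np.allclose(pooled, pooled[0]):
        raise DegenerateDataError("all observations tied; rank test undefined")
    ranks = sps.rankdata(pooled)
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    rank_groups = [ranks[bounds[i]:bounds[i + 1]] for i in range(k)]
    rank_means = [rg.mean() for rg in rank_groups]

    h = float(sps.kruskal(*groups).statistic)
    s2 = (np.sum(ranks**2) - n_total * (n_total + 1) ** 2 / 4.0) / (n_total - 1)
    df_resid = n_total - k
    var_scale = s2 * (n_total - 1 - h) / df_resid
    if var_scale <= 0:
        raise DegenerateDataError("rank variance collapsed (near-perfect separation)")

    rows = []
    nc = sizes[control_index]
    for i in range(k):
        if i == control_index:
            continue
        est = rank_means[i] - rank_means[control_index]
        se = np.sqrt(var_scale * (1.0 / sizes[i] + 1.0 / nc))
        t = est / se
        rows.append({"estimate": est, "statistic": t,
                     "raw_p": 2.0 * sps.t.sf(abs(t), df_resid)})
    raw = [r["raw_p"] for r in rows]
    adj = bh_adjust(raw)
    out = pd.DataFrame(rows)
    out["adjusted_p"] = np.clip(np.maximum(adj, raw), 0.0, 1.0)
    out["significant"] = out["adjusted_p"] < alpha
    out["method"] = "conover_iman_bh"
    return out


def _wilcoxon_ranksum(a: np.ndarray, b: np.ndarray) -> float:
    return float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def _assumptions_ok(shapiro_p: float, bf_p: float, alpha: float) -> bool:
    if np.isnan(shapiro_p):
        return False
    if shapiro_p < alpha:
        return False
    return not (not np.isnan(bf_p) and bf_p < alpha)


def route_and_test(d: GroupedData, alpha: float = 0.05,
                   seed: int | None = None) -> StatRoute:
    """Full assumption-routed analysis of one response variable.

    Performs both contrast families — accessions vs the control accession
    within each treatment, and treatments vs the control treatment within
    each accession — each corrected within its own family.
    """
    shapiro_p, bf_p = check_assumptions(d)
    transform = "none"
    working = d.values
    if not _assumptions_ok(shapiro_p, bf_p, alpha) and np.all(d.values > 0):
        logged = GroupedData(np.log(d.values), d.factors,
                             d.control_accession, d.control_treatment,
                             d.accession_col, d.treatment_col)
        s2p, b2p = check_assumptions(logged)
        if _assumptions_ok(s2p, b2p, alpha):
            transform = "log"
            working = logged.values
            shapiro_p, bf_p = s2p, b2p
    branch = "parametric" if _assumptions_ok(shapiro_p, bf_p, alpha) else "nonparametric"

    frame = d.factors.copy()
    frame["value"] = working
    cells = d.cell_labels()
    omnibus = _omnibus(frame, d.factor_cols(), cells, branch)

    child_seeds = np.random.SeedSequence(seed).spawn(64)
    seed_iter = iter(child_seeds)
    rows = []
    has_acc = d.accession_col in frame.columns
    has_trt = d.treatment_col in frame.columns

    def run_family(family: str, sub: pd.DataFrame, by_col: str, control_label: str,
                   context: str) -> None:
        labels = [l for l in sub[by_col].unique()]
        if control_label not in labels or len(labels) < 2:
            return
        labels = [control_label] + sorted(str(l) for l in labels if l != control_label)
        groups = [sub.loc[sub[by_col].astype(str) == str(l), "value"].to_numpy()
                  for l in labels]
        if any(len(g) < 2 for g in groups):
            return
        try:
            if branch == "parametric":
                res = dunnett(groups, 0, alpha=alpha,
                              rng=np.random.default_rng(next(seed_iter)))
            elif len(groups) == 2:
                p = _wilcoxon_ranksum(groups[1], groups[0])
                res = pd.DataFrame({
                    "estimate": [np.median(groups[1]) - np.median(groups[0])],
                    "statistic": [np.nan], "raw_p": [p], "adjusted_p": [p],
                    "significant": [p < alpha], "method": "wilcoxon_ranksum",
                })
            else:
                res = conover_iman_bh(groups, 0, alpha=alpha)
        except DegenerateDataError:
            return
        for lbl, (_, r) in zip(labels[1:], res.iterrows()):
            rows.append({
                "family": family,
                "contrast": f"{lbl} vs {control_label}" + (f" | {context}" if context else ""),
                "estimate": r["estimate"],
                "raw_p": r["raw_p"],
                "adjusted_p": r["adjusted_p"],
                "significant": bool(r["significant"]),
                "method": r["method"],
                "branch": branch,
            })

    if has_acc and has_trt:
        for trt, sub in frame.groupby(d.treatment_col, sort=True):
            run_family("inter_accession", sub, d.accession_col,
                       d.control_accession, f"{d.treatment_col}={trt}")
        for acc, sub in frame.groupby(d.accession_col, sort=True):
            run_family("intra_accession", sub, d.treatment_col,
                       d.control_treatment, f"{d.accession_col}={acc}")
    elif has_acc:
        run_family("inter_accession", frame, d.accession_col, d.control_accession, "")
    elif has_trt:
        run_family("intra_accession", frame, d.treatment_col, d.control_treatment, "")

    comparisons = pd.DataFrame(
        rows, columns=["family", "contrast", "estimate", "raw_p", "adjusted_p",
                       "significant", "method", "branch"])
    return StatRoute(shapiro_p=shapiro_p, brown_forsythe_p=bf_p,
                     transform_applied=transform, branch=branch,
                     omnibus=omnibus, comparisons=comparisons, alpha=alpha)


def _omnibus(frame: pd.DataFrame, factor_cols: list[str], cells: pd.Series,
             branch: str) -> dict:
    if branch == "parametric":
        usable = [c for c in factor_cols if frame[c].nunique() > 1]
        if not usable:
            return {}
        rhs = "*".join(f"C({c})" for c in usable)
        try:
            model = smf.ols(f"value ~ {rhs}", data=frame).fit()
            table = sm.stats.anova_lm(model, typ=2)
            return {str(idx): float(p) for idx, p in table["PR(>F)"].items()
                    if np.isfinite(p)}
        except Exception:
            return {}
    groups = [frame.loc[(cells == c).to_numpy(), "value"].to_numpy()
              for c in cells.unique()]
    groups = [g for g in groups if len(g) > 0]
    try:
        kw = sps.kruskal(*groups)
        return {"kruskal_wallis": float(kw.pvalue)}
    except ValueError:
        return {"kruskal_wallis": 1.0}


def significance_stars(p: float) -> str:
    """Figure-legend star annotation: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
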