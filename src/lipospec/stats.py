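"""The study-style statistical layer.

Two-group comparisons follow a normality gate: each group is tested for
Gaussianity and, if both pass, an unpaired two-tailed t-test is used,
otherwise a two-tailed Mann-Whitney test. With the small group sizes
typical here (n = 5-6) and parameters estimated from the data, the gate
uses the Lilliefors-corrected Kolmogorov-Smirnov test (plain KS against
fitted parameters is anti-conservative). Correlations follow the same
gate: Pearson when both variables pass, Spearman otherwise.

PCA of lipid profiles uses the standard metabolomics preprocessing:
rows (samples) are normalised to total area, then each column is
mean-centred and divided by the square root of its standard deviation
(Pareto scaling) before the decomposition. Component signs are fixed by
making the largest-magnitude loading positive.

No multiple-testing correction is applied by default, matching
per-measurand reporting; a Benjamini-Hochberg option exists.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InsufficientDataError, UndefinedStatisticError

__all__ = [
    "GroupComparison",
    "PcaResult",
    "normality_gate",
    "compare_groups",
    "fold_change",
    "correlate",
    "pca_lipid_profiles",
    "build_summary_table",
]


@dataclass
class GroupComparison:
    """Everything reported for one two-group comparison."""

    measurand: str
    group_labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    sds: tuple[float, float]
    sems: tuple[float, float]
    fold_change: float  # mean1 / mean2; NaN when mean2 == 0
    test_used: str  # "student_t" | "mann_whitney"
    p_value: float
    significant: bool
    alpha: float = 0.05
    normality_gate: str = "lilliefors"


@dataclass
class PcaResult:
    """Scores, loadings and explained-variance fractions of a lipid-profile
    PCA, with the preprocessing recorded."""

    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # peaks x components
    explained_variance: np.ndarray  # fractions, non-increasing
    peak_ids: list[str]
    preprocessing: dict


def normality_gate(x: np.ndarray, alpha: float = 0.05) -> bool:
    """True when Gaussianity is not rejected at ``alpha``.

    Uses the Lilliefors-corrected KS test (parameters estimated from the
    sample). Groups too small to test (n < 4) or with zero variance
    cannot pass a distributional test meaningfully: zero-variance data
    fail the gate; n < 4 passes (no evidence against normality).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        return True
    if np.std(x) == 0:
        return False
    _, p = lilliefors(x, dist="norm", pvalmethod="table")
    return bool(p >= alpha)


def fold_change(mean_a: float, mean_b: float, decimals: int | None = None) -> float:
    """Ratio of group means (a over b); optionally rounded half-even to
    table precision. Undefined (NaN) when ``mean_b`` is zero."""
    if mean_b == 0:
        return math.nan
    fc = mean_a / mean_b
    if decimals is not None:
        fc = float(np.round(fc, decimals))
    return fc


def compare_groups(
    a,
    b,
    alpha: float = 0.05,
    measurand: str = "",
    group_labels: tuple[str, str] = ("group1", "group2"),
    t_variant: str = "welch",
) -> GroupComparison:
    """Normality-gated two-group comparison.

    Both groups passing the gate selects the unpaired two-tailed t-test
    (Welch by default; ``t_variant='pooled'`` for equal variances);
    otherwise the two-tailed Mann-Whitney test is used, exact for
    n <= 8 per group when the data permit.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs >= 2 finite values")

    gate = normality_gate(a, alpha) and normality_gate(b, alpha)
    if gate:
        test_used = "student_t"
        _, p = sps.ttest_ind(a, b, equal_var=(t_variant == "pooled"))
    else:
        test_used = "mann_whitney"
        method = "exact" if max(a.size, b.size) <= 8 else "asymptotic"
        try:
            _, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        except ValueError:  # ties with exact method
            _, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    p = float(p)
    if math.isnan(p):  # degenerate (e.g. both groups constant and equal)
        p = 1.0

    mean_a, mean_b = float(a.mean()), float(b.mean())
    sd_a = float(a.std(ddof=1))
    sd_b = float(b.std(ddof=1))
    return GroupComparison(
        measurand=measurand,
        group_labels=group_labels,
        n=(a.size, b.size),
        means=(mean_a, mean_b),
        sds=(sd_a, sd_b),
        sems=(sd_a / math.sqrt(a.size), sd_b / math.sqrt(b.size)),
        fold_change=fold_change(mean_a, mean_b),
        test_used=test_used,
        p_value=p,
        significant=bool(p < alpha),
        alpha=alpha,
    )


def correlate(x, y, alpha: float = 0.05) -> tuple[str, float, float]:
    """Gate-selected correlation: ('pearson'|'spearman', r, two-tailed p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InsufficientDataError("correlate needs equal-length arrays, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    if normality_gate(x, alpha) and normality_gate(y, alpha):
        r, p = sps.pearsonr(x, y)
        return "pearson", float(r), float(p)
    r, p = sps.spearmanr(x, y)
    return "spearman", float(r), float(p)


def pca_lipid_profiles(
    areas,
    n_components: int | None = None,
    peak_ids: list[str] | None = None,
) -> PcaResult:
    """PCA of a samples x peaks area matrix after total-area normalisation
    and Pareto scaling.

    Columns that are constant after normalisation are dropped with a
    warning. A fully degenerate matrix (all samples identical) returns
    zero scores and zero explained variance.
    """
    if isinstance(areas, pd.DataFrame):
        peak_ids = list(areas.columns)
        X = areas.to_numpy(dtype=float)
    else:
        X = np.asarray(areas, dtype=float)
        if peak_ids is None:
            peak_ids = [f"peak_{j}" for j in range(X.shape[1])]
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise InsufficientDataError("need >= 3 samples and >= 2 peaks")
    if not np.isfinite(X).all():
        raise ValueError("area matrix contains missing or non-finite cells")

    row_sums = X.sum(axis=1, keepdims=True)
    if np.any(row_sums <= 0):
        raise UndefinedStatisticError("sample with non-positive total area")
    Xn = X / row_sums

    sd = Xn.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = [pid for pid, k in zip(peak_ids, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropping constant peak(s) after normalisation: {', '.join(dropped)}",
            stacklevel=2,
        )
    preprocessing = {
        "normalization": "total_area",
        "scaling": "pareto",
        "dropped_constant_peaks": dropped,
    }
    kept_ids = [pid for pid, k in zip(peak_ids, keep) if k]
    n_samples = X.shape[0]
    if not keep.any():
        k = n_components or 1
        return PcaResult(
            scores=np.zeros((n_samples, k)),
            loadings=np.zeros((0, k)),
            explained_variance=np.zeros(k),
            peak_ids=[],
            preprocessing=preprocessing,
        )

    Xp = (Xn[:, keep] - Xn[:, keep].mean(axis=0)) / np.sqrt(sd[keep])
    k = min(n_samples - 1, Xp.shape[1])
    if n_components is not None:
        k = min(k, n_components)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Xp)
    loadings = pca.components_.T  # peaks x components
    # deterministic sign: largest-magnitude loading positive per component
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PcaResult(
        scores=scores,
        loadings=loadings,
        explained_variance=pca.explained_variance_ratio_,
        peak_ids=kept_ids,
        preprocessing=preprocessing,
    )


def build_summary_table(
    cohort: pd.DataFrame,
    measurands: list[str],
    group_pairs: list[tuple[dict, dict]],
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Table-style summary: per measurand and group pair, the group means,
    SDs, SEMs, fold change, gated test and p-value ('NS' when p >= alpha).

    ``group_pairs`` selects rows by column values, e.g.
    ``({"genotype": "CpKO", "age_months": 6}, {"genotype": "WT",
    "age_months": 6})``. Missing values are excluded pairwise with the
    per-cell n reported. ``fdr=True`` appends Benjamini-Hochberg adjusted
    p-values.
    """
    for m in measurands:
        if m not in cohort.columns:
            raise ConfigurationError(f"measurand {m!r} not in cohort table")

    def _select(sel: dict) -> pd.DataFrame:
        mask = np.ones(len(cohort), dtype=bool)
        for col, val in sel.items():
            mask &= (cohort[col] == val).to_numpy()
        return cohort[mask]

    def _label(sel: dict) -> str:
        return "/".join(str(v) for v in sel.values())

    rows = []
    for sel1, sel2 in group_pairs:
        g1, g2 = _select(sel1), _select(sel2)
        for m in measurands:
            a = g1[m].to_numpy(dtype=float)
            b = g2[m].to_numpy(dtype=float)
            cmp = compare_groups(
                a, b, alpha=alpha, measurand=m,
                group_labels=(_label(sel1), _label(sel2)),
            )
            rows.append(
                {
                    "measurand": m,
                    "group1": cmp.group_labels[0],
                    "group2": cmp.group_labels[1],
                    "n1": cmp.n[0],
                    "n2": cmp.n[1],
                    "mean1": cmp.means[0],
                    "sd1": cmp.sds[0],
                    "sem1": cmp.sems[0],
                    "mean2": cmp.means[1],
                    "sd2": cmp.sds[1],
                    "sem2": cmp.sems[1],
                    "fold_change": cmp.fold_change,
                    "test_used": cmp.test_used,
                    "p_value": cmp.p_value,
                    "p_display": "NS" if cmp.p_value >= alpha else f"{cmp.p_value:.4f}",
                    "significant": cmp.significant,
                }
            )
    table = pd.DataFrame(rows)
    if fdr and len(table):
        _, p_adj, _, _ = multipletests(table["p_value"], method="fdr_bh")
        table["p_adjusted_bh"] = p_adj
    return table
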