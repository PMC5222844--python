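"""Statistics layer: ROC AUC with bootstrap CI and effect classes, Youden's
index, two-sample Kolmogorov–Smirnov with Bonferroni correction, and
mixed-design (two-way repeated-measures) ANOVA.

The AUC is the Mann–Whitney pairwise probability P(b > a) + ½P(b = a),
folded to the interval (0.5–1) so that only effect magnitude is reported;
AUC > 0.64 counts as a medium and AUC > 0.71 as a strong effect. The 95%
confidence interval is a percentile bootstrap resampling animals within each
group, each replicate folded the same way.

The mixed ANOVA is the classical univariate partition for a balanced design
with one between-subject factor (group/strain/age) and one within-subject
factor (time bin): the group effect is tested against between-subject error,
time and group×time against the within-subject error. Post-hoc per-bin
two-group comparisons are Bonferroni-corrected across bins. No sphericity
correction is applied by default; Greenhouse–Geisser is available as a
toggle and noted in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError

AUC_MEDIUM = 0.64
AUC_STRONG = 0.71


# ---------------------------------------------------------------------------
# ROC AUC / Youden
# ---------------------------------------------------------------------------

@dataclass
class AUCResult:
    auc: float  # folded to [0.5, 1]
    raw_auc: float  # orientation-preserving P(b > a) + 0.5 P(b = a)
    ci_lo: float
    ci_hi: float
    effect_class: str  # none / medium / strong
    n_boot: int


def classify_auc_effect(auc: float) -> str:
    if auc > AUC_STRONG:
        return "strong"
    if auc > AUC_MEDIUM:
        return "medium"
    return "none"


def _pairwise_auc(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """P(b > a) + 0.5 P(b = a); inputs may carry leading batch dimensions."""
    diff = b[..., None, :] - a[..., :, None]
    gt = np.count_nonzero(diff > 0, axis=(-2, -1))
    eq = np.count_nonzero(diff == 0, axis=(-2, -1))
    return (gt + 0.5 * eq) / (a.shape[-1] * b.shape[-1])


def auc_analysis(
    a, b, n_boot: int = 10_000, seed: int | None = None, ci: float = 95.0
) -> AUCResult:
    """ROC AUC of group ``b`` versus group ``a`` with a bootstrap CI.

    Both groups need at least two observations (animals). The point estimate
    and every bootstrap replicate are folded to (0.5–1); the CI is the
    percentile interval of the folded replicates, widened if necessary to
    contain the point estimate.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError(
            f"need >=2 values per group, got {a.size} and {b.size}"
        )
    n_pairs = a.size * b.size
    diff = b[None, :] - a[:, None]
    gt = np.count_nonzero(diff > 0)
    eq = np.count_nonzero(diff == 0)
    raw = (gt + 0.5 * eq) / n_pairs
    # fold on the pair counts so the result is the exactly-rounded rational
    folded = max(gt + 0.5 * eq, (n_pairs - gt - eq) + 0.5 * eq) / n_pairs
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, a.size, size=(n_boot, a.size))
    ib = rng.integers(0, b.size, size=(n_boot, b.size))
    reps = _pairwise_auc(a[ia], b[ib])
    reps = np.maximum(reps, 1.0 - reps)
    alpha = (100.0 - ci) / 2.0
    lo, hi = np.percentile(reps, [alpha, 100.0 - alpha])
    return AUCResult(
        auc=folded,
        raw_auc=raw,
        ci_lo=float(min(lo, folded)),
        ci_hi=float(max(hi, folded)),
        effect_class=classify_auc_effect(folded),
        n_boot=n_boot,
    )


def youden_optimal(values, labels) -> tuple[float, float, float]:
    """Threshold maximizing Youden's J = sensitivity + specificity − 1.

    ``labels`` marks the positive class (expected to take higher values; an
    epoch is called positive when its value exceeds the threshold).
    Candidates are the midpoints of consecutive sorted unique values; ties on
    J are broken toward higher specificity, then the lower threshold.
    Returns ``(threshold, sensitivity, specificity)``.
    """
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels, dtype=bool).ravel()
    if labels.all() or not labels.any():
        raise InsufficientDataError("both classes must be present")
    uniq = np.unique(values)
    if uniq.size == 1:
        candidates = np.array([uniq[0]])
    else:
        candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    best = None
    for th in candidates:
        pred = values > th
        sens = np.count_nonzero(pred & labels) / n_pos
        spec = np.count_nonzero(~pred & ~labels) / n_neg
        key = (sens + spec - 1.0, spec, -th)
        if best is None or key > best[0]:
            best = (key, (float(th), float(sens), float(spec)))
    return best[1]


# ---------------------------------------------------------------------------
# Kolmogorov–Smirnov
# ---------------------------------------------------------------------------

@dataclass
class KSResult:
    d: float
    p_raw: float
    p_adjusted: float
    m_comparisons: int


def ks_two_sample(x, y, m_comparisons: int = 1, method: str = "asymp") -> KSResult:
    """Two-sample KS test (sup-norm ECDF distance) with Bonferroni correction.

    ``method`` is passed to :func:`scipy.stats.ks_2samp` ('asymp' by default;
    'exact' is advisable for very small samples, 'auto' lets scipy choose).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError("both samples must be non-empty")
    res = sps.ks_2samp(x, y, method=method)
    p_adj = bonferroni_adjust([res.pvalue], m_comparisons)[0]
    return KSResult(
        d=float(res.statistic),
        p_raw=float(res.pvalue),
        p_adjusted=float(p_adj),
        m_comparisons=m_comparisons,
    )


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni: p_adj = min(1, m·p). ``m`` defaults to the family size."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be a positive family size")
    return np.minimum(1.0, m * p)


# ---------------------------------------------------------------------------
# mixed-design ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    effects: pd.DataFrame  # index: group/time/interaction; SS, F, df1, df2, p
    posthoc: pd.DataFrame  # per time bin: comparison, t, p_raw, p_adjusted
    sphericity_correction: str  # 'none' or 'greenhouse-geisser'
    ss_subjects: float = float("nan")  # between-subject error SS
    ss_error: float = float("nan")  # within-subject error SS


def mixed_anova(
    values: np.ndarray,
    groups,
    greenhouse_geisser: bool = False,
    posthoc: bool = True,
) -> AnovaResult:
    """Two-way repeated-measures ANOVA, between factor = group, within = time.

    ``values`` has shape ``(n_subjects, n_bins)``; ``groups`` labels each
    subject. The design must be complete (no NaN; every subject measured in
    every bin) with at least two subjects per group.
    """
    y = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if y.ndim != 2:
        raise ValueError("values must be a (n_subjects, n_bins) array")
    if np.isnan(y).any():
        raise InsufficientDataError("missing cells: the design must be complete")
    n, t = y.shape
    if groups.shape[0] != n:
        raise ValueError("groups length must match the number of subjects")
    labels, ginv = np.unique(groups, return_inverse=True)
    g = labels.size
    sizes = np.bincount(ginv)
    if g < 2 or t < 2 or np.any(sizes < 2):
        raise InsufficientDataError(
            "need >=2 groups, >=2 time bins and >=2 subjects per group"
        )

    grand = y.mean()
    subj_means = y.mean(axis=1)  # per subject
    time_means = y.mean(axis=0)  # per bin
    group_means = np.array([subj_means[ginv == j].mean() for j in range(g)])
    cell_means = np.vstack([y[ginv == j].mean(axis=0) for j in range(g)])

    ss_group = t * np.sum(sizes * (group_means - grand) ** 2)
    ss_subj = t * np.sum((subj_means - group_means[ginv]) ** 2)
    ss_time = n * np.sum((time_means - grand) ** 2)
    ss_inter = np.sum(
        sizes[:, None]
        * (cell_means - group_means[:, None] - time_means[None, :] + grand) ** 2
    )
    resid = y - subj_means[:, None] - cell_means[ginv] + group_means[ginv][:, None]
    ss_error = np.sum(resid**2)

    df_group, df_subj = g - 1, n - g
    df_time, df_inter, df_error = t - 1, (g - 1) * (t - 1), (n - g) * (t - 1)

    eps = 1.0
    correction = "none"
    if greenhouse_geisser:
        eps = _gg_epsilon(y, ginv, g)
        correction = "greenhouse-geisser"

    def f_and_p(ss, df1, ss_err, df2, corrected=False):
        e = eps if corrected else 1.0
        f = (ss / df1) / (ss_err / df2)
        p = float(sps.f.sf(f, df1 * e, df2 * e))
        return float(ss), float(f), df1, df2, p

    rows = {
        "group": f_and_p(ss_group, df_group, ss_subj, df_subj),
        "time": f_and_p(ss_time, df_time, ss_error, df_error, corrected=True),
        "interaction": f_and_p(ss_inter, df_inter, ss_error, df_error, corrected=True),
    }
    effects = pd.DataFrame(rows, index=["SS", "F", "df1", "df2", "p"]).T
    effects[["df1", "df2"]] = effects[["df1", "df2"]].astype(int)

    ph_rows = []
    if posthoc:
        pairs = [(i, j) for i in range(g) for j in range(i + 1, g)]
        m = t * len(pairs)
        for bin_idx in range(t):
            for i, j in pairs:
                xi = y[ginv == i, bin_idx]
                xj = y[ginv == j, bin_idx]
                tt = sps.ttest_ind(xi, xj)
                ph_rows.append(
                    {
                        "bin": bin_idx,
                        "comparison": f"{labels[i]} vs {labels[j]}",
                        "t": float(tt.statistic),
                        "p_raw": float(tt.pvalue),
                        "p_adjusted": float(min(1.0, m * tt.pvalue)),
                    }
                )
    posthoc_df = pd.DataFrame(
        ph_rows, columns=["bin", "comparison", "t", "p_raw", "p_adjusted"]
    )
    return AnovaResult(
        effects=effects,
        posthoc=posthoc_df,
        sphericity_correction=correction,
        ss_subjects=float(ss_subj),
        ss_error=float(ss_error),
    )


def _gg_epsilon(y: np.ndarray, ginv: np.ndarray, g: int) -> float:
    """Greenhouse–Geisser epsilon from the pooled within-group covariance."""
    t = y.shape[1]
    pooled = np.zeros((t, t))
    dof = 0
    for j in range(g):
        yj = y[ginv == j]
        pooled += (yj.shape[0] - 1) * np.cov(yj, rowvar=False)
        dof += yj.shape[0] - 1
    s = pooled / dof
    mean_diag = np.trace(s) / t
    mean_all = s.mean()
    row_means = s.mean(axis=1)
    num = (t * (mean_diag - mean_all)) ** 2
    den = (t - 1) * (np.sum(s**2) - 2 * t * np.sum(row_means**2) + t**2 * mean_all**2)
    return float(np.clip(num / den, 1.0 / (t - 1), 1.0))
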