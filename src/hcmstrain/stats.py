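"""Diagnostic statistics: group comparisons, ROC with Hanley-McNeil errors,
the two-threshold carrier rule, Bland-Altman agreement, and random-intercept
multilevel regression.

The carrier-identification rule combines a morphological marker (septal-to-
lateral wall-thickness ratio, SL > 1.2) with a functional one (basal lateral
peak diastolic circumferential strain rate, DCSR < 105 %/s).  Subjects
positive on both are test-positive, negative on both test-negative, and the
two mixed quadrants are tallied separately; predictive values use only the
concordant quadrants, which is how such two-threshold screens are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "ROCResult",
    "AUCComparison",
    "ClassificationResult",
    "AgreementResult",
    "MixedModelResult",
    "compare_groups",
    "hanley_mcneil_se",
    "roc_analysis",
    "compare_aucs",
    "classify_rule",
    "bland_altman",
    "fit_multilevel",
    "anova_bonferroni",
]


# ---------------------------------------------------------------------------
# two-sample comparison with a normality gate


@dataclass(frozen=True)
class GroupComparison:
    test: str  # "t" or "mann-whitney"
    statistic: float
    p_value: float
    mean1: float
    mean2: float
    n1: int
    n2: int


def compare_groups(values1, values2, normality_alpha: float = 0.05,
                   force: str | None = None) -> GroupComparison:
    """Two-sample comparison: classical Student t-test when both samples
    pass Shapiro-Wilk normality at ``normality_alpha``, Mann-Whitney U
    otherwise (``force`` overrides with "t" or "mann-whitney")."""
    x = np.asarray(values1, dtype=float)
    y = np.asarray(values2, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 observations per group")
    if force is None:
        normal = (
            sps.shapiro(x).pvalue > normality_alpha
            and sps.shapiro(y).pvalue > normality_alpha
        )
        test = "t" if normal else "mann-whitney"
    else:
        test = force
    if test == "t":
        res = sps.ttest_ind(x, y, equal_var=True)
    elif test == "mann-whitney":
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean1=float(x.mean()),
        mean2=float(y.mean()),
        n1=len(x),
        n2=len(y),
    )


# ---------------------------------------------------------------------------
# ROC


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil closed-form standard error of a trapezoid AUC:

    SE^2 = [A(1-A) + (n1-1)(Q1-A^2) + (n2-1)(Q2-A^2)] / (n1 n2),
    Q1 = A/(2-A),  Q2 = 2A^2/(1+A).
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError("AUC outside [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one subject per class")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


@dataclass(frozen=True)
class ROCResult:
    auc: float
    se_auc: float
    optimal_cutoff: float
    sensitivity_pct: float  # at the optimal cutoff
    specificity_pct: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    direction: str  # "greater": score > cutoff is test-positive
    n_pos: int
    n_neg: int
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)


def roc_analysis(scores, labels, direction: str = "greater") -> ROCResult:
    """ROC of a continuous score against binary labels.

    AUC equals the Mann-Whitney pairwise win fraction (ties half credit),
    identical to the trapezoid rule over the empirical ROC; its SE is the
    Hanley-McNeil closed form; the reported cutoff maximizes Youden's
    J = sensitivity + specificity - 1.  ``direction="less"`` declares low
    scores test-positive (e.g. a reduced strain rate).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    keep = np.isfinite(s)
    s, y = s[keep], y[keep]
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    w = s if direction == "greater" else -s

    # AUC via rank statistic (= exhaustive pairwise comparison with ties 0.5)
    ranks = sps.rankdata(w)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    # empirical ROC curve over unique thresholds
    order = np.argsort(-w, kind="mergesort")
    ws, ys = w[order], y[order]
    distinct = np.r_[np.where(np.diff(ws))[0], len(ws) - 1]
    tp = np.cumsum(ys)[distinct]
    fp = np.cumsum(~ys)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thr = np.r_[np.inf, ws[distinct]]

    j = tpr - fpr
    i_opt = int(np.argmax(j))
    cutoff = thr[i_opt] if direction == "greater" else -thr[i_opt]
    return ROCResult(
        auc=float(auc),
        se_auc=hanley_mcneil_se(float(auc), n_pos, n_neg),
        optimal_cutoff=float(cutoff),
        sensitivity_pct=100.0 * float(tpr[i_opt]),
        specificity_pct=100.0 * float(1.0 - fpr[i_opt]),
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        direction=direction,
        n_pos=n_pos,
        n_neg=n_neg,
        scores=s,
        labels=y,
    )


@dataclass(frozen=True)
class AUCComparison:
    delta_auc: float
    z: float
    p_value: float
    r: float  # correlation between the paired AUC estimates


def compare_aucs(roc1: ROCResult, roc2: ROCResult,
                 r: float | None = None) -> AUCComparison:
    """Hanley-McNeil z-test for two (possibly correlated) AUCs measured on
    the same subjects:

        z = (A1 - A2) / sqrt(SE1^2 + SE2^2 - 2 r SE1 SE2)

    If ``r`` is not given it is estimated as the mean of the within-class
    Pearson correlations of the two scores (the quantity the published
    lookup table is entered with; the table value is approximated by the
    correlation itself).  ``r=0`` reduces to the independent-samples test.
    """
    if r is None:
        if roc1.scores is None or roc2.scores is None:
            raise ValueError("need paired scores (or an explicit r)")
        if len(roc1.scores) != len(roc2.scores) or not np.array_equal(
            roc1.labels, roc2.labels
        ):
            raise ValueError("AUCs must be computed on the same subjects")
        y = roc1.labels
        rs = []
        for cls in (y, ~y):
            if cls.sum() >= 3:
                rr = np.corrcoef(roc1.scores[cls], roc2.scores[cls])[0, 1]
                if np.isfinite(rr):
                    rs.append(rr)
        r = float(np.mean(rs)) if rs else 0.0
    delta = roc1.auc - roc2.auc
    var = roc1.se_auc**2 + roc2.se_auc**2 - 2.0 * r * roc1.se_auc * roc2.se_auc
    if var <= 0.0:
        z = 0.0 if delta == 0.0 else np.sign(delta) * np.inf
    else:
        z = delta / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return AUCComparison(delta_auc=float(delta), z=float(z),
                        p_value=float(p), r=float(r))


# ---------------------------------------------------------------------------
# two-threshold classification rule


@dataclass(frozen=True)
class ClassificationResult:
    cutoffs: tuple[float, float]  # (SL ratio, DCSR %/s)
    # quadrant counts as {"carrier": n, "control": n}
    positive: dict
    negative: dict
    sl_only: dict
    dcsr_only: dict
    excluded: dict  # missing either metric
    sensitivity_pct: float
    specificity_pct: float
    ppv_pct: float
    npv_pct: float

    @property
    def n_carriers(self) -> int:
        return sum(d["carrier"] for d in
                   (self.positive, self.negative, self.sl_only, self.dcsr_only))

    @property
    def n_controls(self) -> int:
        return sum(d["control"] for d in
                   (self.positive, self.negative, self.sl_only, self.dcsr_only))


def classify_rule(
    sl_ratio,
    peak_dcsr_lateral,
    is_carrier,
    cutoffs: tuple[float, float] = (1.2, 105.0),
) -> ClassificationResult:
    """Apply the two-threshold screen SL > c1 AND DCSR < c2.

    Subjects high on both metrics' abnormal sides are test-positive, low on
    both test-negative; discordant subjects fall into the two mixed
    quadrants.  PPV/NPV are computed on the concordant quadrants only;
    sensitivity is the fraction of carriers that are test-positive and
    specificity the fraction of controls that are not.  Subjects missing
    either metric are excluded and counted.  Empty denominators yield NaN.
    """
    sl = np.asarray(sl_ratio, dtype=float)
    dcsr = np.asarray(peak_dcsr_lateral, dtype=float)
    car = np.asarray(is_carrier).astype(bool)
    if not len(sl) == len(dcsr) == len(car):
        raise ValueError("metric and label arrays must align")
    present = np.isfinite(sl) & np.isfinite(dcsr)
    c1, c2 = cutoffs
    sl_pos = sl > c1
    dc_pos = dcsr < c2

    def count(mask):
        m = mask & present
        return {"carrier": int((m & car).sum()), "control": int((m & ~car).sum())}

    pos = count(sl_pos & dc_pos)
    neg = count(~sl_pos & ~dc_pos)
    sl_only = count(sl_pos & ~dc_pos)
    dc_only = count(~sl_pos & dc_pos)
    excl = {"carrier": int((~present & car).sum()),
            "control": int((~present & ~car).sum())}

    def pct(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    n_car = int((present & car).sum())
    n_ctl = int((present & ~car).sum())
    return ClassificationResult(
        cutoffs=(float(c1), float(c2)),
        positive=pos,
        negative=neg,
        sl_only=sl_only,
        dcsr_only=dc_only,
        excluded=excl,
        sensitivity_pct=pct(pos["carrier"], n_car),
        specificity_pct=pct(n_ctl - pos["control"], n_ctl),
        ppv_pct=pct(pos["carrier"], pos["carrier"] + pos["control"]),
        npv_pct=pct(neg["control"], neg["carrier"] + neg["control"]),
    )


# ---------------------------------------------------------------------------
# agreement


@dataclass(frozen=True)
class AgreementResult:
    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float
    coefficient_of_variability: float
    n: int


def bland_altman(measurements1, measurements2) -> AgreementResult:
    """Bland-Altman agreement of paired measurements.

    Limits of agreement are mean +- 1.96 SD of the differences.  The
    coefficient of variability averages, over pairs, the SD of the two
    values (|d|/sqrt(2)) divided by their mean.
    """
    a = np.asarray(measurements1, dtype=float)
    b = np.asarray(measurements2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two aligned 1-D measurement vectors")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if len(a) < 2:
        raise ValueError("need at least 2 measurement pairs")
    d = a - b
    md, sd = float(d.mean()), float(d.std(ddof=1))
    pair_mean = (a + b) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = np.abs(d) / np.sqrt(2.0) / np.abs(pair_mean)
    cov = float(np.nanmean(cov[np.isfinite(cov)])) if np.isfinite(cov).any() else 0.0
    return AgreementResult(
        mean_difference=md,
        sd_difference=sd,
        loa_lower=md - 1.96 * sd,
        loa_upper=md + 1.96 * sd,
        coefficient_of_variability=cov,
        n=len(a),
    )


# ---------------------------------------------------------------------------
# multilevel regression


@dataclass(frozen=True)
class MixedModelResult:
    outcome: str
    fixed_effects: pd.DataFrame  # beta, se, p per term
    subject_variance: float
    slice_variance: float
    residual_variance: float
    converged: bool
    interactions: pd.DataFrame | None = None
    model: object = field(repr=False, default=None)

    def beta(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "beta"])

    def se(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "se"])

    def ci95(self, term: str) -> tuple[float, float]:
        b, s = self.beta(term), self.se(term)
        return b - 1.96 * s, b + 1.96 * s


def fit_multilevel(
    table: pd.DataFrame,
    outcome: str,
    fixed: list[str],
    subject_col: str = "subject_id",
    slice_col: str | None = "slice",
    screen_interactions: bool = False,
) -> MixedModelResult:
    """Linear mixed model with random intercepts for subject and, when
    ``slice_col`` is given, slice within subject (segments nested in slices
    nested in subjects), fitted by maximum likelihood.

    ``screen_interactions`` additionally fits each pairwise interaction of
    the fixed effects (one at a time, on top of the main-effects model) and
    reports its coefficient and p-value.  Singular / non-converged fits are
    reported via ``converged``, never masked.
    """
    import statsmodels.formula.api as smf

    data = table.dropna(subset=[outcome, *fixed]).copy()
    if data[subject_col].nunique() < 3:
        raise ValueError("need at least 3 subjects for a multilevel fit")
    rhs = " + ".join(fixed) if fixed else "1"
    formula = f"{outcome} ~ {rhs}"
    vc = {}
    if slice_col is not None and data[slice_col].nunique() > 1:
        vc = {"slice": f"0 + C({slice_col})"}

    def _fit(f):
        model = smf.mixedlm(f, data, groups=data[subject_col],
                            re_formula="1", vc_formula=vc or None)
        with np.errstate(all="ignore"):
            return model.fit(reml=False, method="lbfgs", maxiter=200)

    res = _fit(formula)
    fe = pd.DataFrame(
        {
            "beta": res.fe_params,
            "se": res.bse_fe,
            "p": res.pvalues[res.fe_params.index],
        }
    )
    subj_var = float(np.asarray(res.cov_re)[0, 0]) if res.cov_re.size else 0.0
    slice_var = float(res.vcomp[0]) if vc and len(res.vcomp) else 0.0

    inter = None
    if screen_interactions and len(fixed) > 1:
        rows = []
        for i in range(len(fixed)):
            for j in range(i + 1, len(fixed)):
                term = f"{fixed[i]}:{fixed[j]}"
                try:
                    ri = _fit(f"{formula} + {term}")
                    name = [ix for ix in ri.fe_params.index if ":" in ix][0]
                    rows.append(
                        {
                            "interaction": term,
                            "beta": float(ri.fe_params[name]),
                            "p": float(ri.pvalues[name]),
                        }
                    )
                except Exception:  # noqa: BLE001 - singular screens reported as NaN
                    rows.append({"interaction": term, "beta": np.nan, "p": np.nan})
        inter = pd.DataFrame(rows)

    return MixedModelResult(
        outcome=outcome,
        fixed_effects=fe,
        subject_variance=subj_var,
        slice_variance=slice_var,
        residual_variance=float(res.scale),
        converged=bool(res.converged),
        interactions=inter,
        model=res,
    )


# ---------------------------------------------------------------------------
# within-slice segment comparison


def anova_bonferroni(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA followed by Bonferroni-adjusted pairwise t-tests.

    Returns one row per pair with the raw and adjusted p
    (p_adj = min(1, m * p)); the ANOVA F and p are attached as attrs.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [v[(g == lab) & np.isfinite(v)] for lab in labels]
    f, p_anova = sps.f_oneway(*samples)
    pairs = []
    m = len(labels) * (len(labels) - 1) // 2
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            t = sps.ttest_ind(samples[i], samples[j], equal_var=True)
            pairs.append(
                {
                    "group1": labels[i],
                    "group2": labels[j],
                    "p_raw": float(t.pvalue),
                    "p_adj": float(min(1.0, m * t.pvalue)),
                    "significant": bool(min(1.0, m * t.pvalue) < alpha),
                }
            )
    out = pd.DataFrame(pairs)
    out.attrs["anova_F"] = float(f)
    out.attrs["anova_p"] = float(p_anova)
    return out
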