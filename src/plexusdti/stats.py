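"""Repeatability and covariate statistics for per-nerve diffusion metrics.

Implements the agreement toolbox used in test–retest nerve DTI studies —
Bland–Altman limits, within-subject coefficient of variation (CV), minimal
detectable difference (MDD), intraclass correlation for absolute agreement
and single measures ICC(A,1), right–left percent differences — plus a
univariate repeated-measures ANOVA over the side × root-level layout with
Mauchly's sphericity test, Greenhouse–Geisser correction, and stepwise
forward selection of between-subject covariates, and ordinary linear
regression of per-subject diffusivities on bodyweight.

Definitions:
    CV  = 100 · SD(paired differences) / mean        (%)
    MDD = 1.96 · SD(paired differences)              (metric units)
    so MDD ≡ 1.96 · (CV/100) · mean, an identity kept exact here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedSeries",
    "BlandAltman",
    "RegressionResult",
    "AnovaReport",
    "bland_altman",
    "cv_percent",
    "mdd",
    "icc_agreement_single",
    "icc_category",
    "rl_percent_diff",
    "rm_anova",
    "rm_anova_stepwise",
    "linreg",
    "repeatability_report",
    "load_supplementary_table",
]

METRICS = ("fa", "md", "ad", "rd")


@dataclass(frozen=True)
class PairedSeries:
    """Matched measurements (x1ᵢ, x2ᵢ) of one metric, e.g. session 1 vs 2."""

    x1: np.ndarray
    x2: np.ndarray
    kind: str = "session"

    def __post_init__(self):
        a, b = np.asarray(self.x1, float), np.asarray(self.x2, float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("paired series must be equal-length 1-D arrays")
        if len(a) < 2:
            raise ValueError("need at least 2 pairs")
        object.__setattr__(self, "x1", a)
        object.__setattr__(self, "x2", b)

    @property
    def diffs(self) -> np.ndarray:
        return self.x1 - self.x2

    @property
    def grand_mean(self) -> float:
        return float(np.concatenate([self.x1, self.x2]).mean())


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    lower: float
    upper: float
    sd_diff: float


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    slope_se: float

    def slope_ci(self, level: float = 0.95, n: int | None = None) -> tuple:
        # normal approximation is adequate at the cohort sizes used here
        z = sps.norm.ppf(0.5 + level / 2)
        return (self.slope - z * self.slope_se, self.slope + z * self.slope_se)


@dataclass(frozen=True)
class AnovaReport:
    """Within-subject effect tests adjusted for entered covariates."""

    effects: dict  # name -> dict(F, df1, df2, p, epsilon, p_gg, mauchly_w, mauchly_p)
    selected_covariates: list
    covariate_p_values: dict  # covariate -> P at its entry test (final step)
    n_subjects: int


def _as_pairs(x1, x2=None) -> PairedSeries:
    if isinstance(x1, PairedSeries):
        return x1
    return PairedSeries(x1=x1, x2=x2)


def bland_altman(x1, x2=None) -> BlandAltman:
    """Mean difference and 95% limits of agreement mean(d) ± 1.96·SD(d),
    with the sample SD (n−1)."""
    p = _as_pairs(x1, x2)
    d = p.diffs
    m = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(mean_diff=m, lower=m - 1.96 * sd, upper=m + 1.96 * sd, sd_diff=sd)


def cv_percent(x1, x2=None, denominator: str = "grand_mean") -> float:
    """Within-subject CV: 100 · SD(paired differences) / mean.

    The "mean" in the denominator defaults to the grand mean over both
    members of every pair; ``denominator='pair_means'`` uses the mean of the
    per-pair averages instead (identical for complete pairs, distinct only
    under weighting schemes).
    """
    p = _as_pairs(x1, x2)
    if denominator == "grand_mean":
        m = p.grand_mean
    elif denominator == "pair_means":
        m = float(((p.x1 + p.x2) / 2).mean())
    else:
        raise ValueError("denominator must be 'grand_mean' or 'pair_means'")
    if m == 0:
        raise ValueError("CV undefined: mean of measurements is zero")
    return float(100.0 * p.diffs.std(ddof=1) / m)


def mdd(x1, x2=None) -> float:
    """Minimal detectable difference: 1.96 · SD(paired differences)."""
    p = _as_pairs(x1, x2)
    return float(1.96 * p.diffs.std(ddof=1))


def mdd_from_cv(mean: float, cv_pct: float) -> float:
    """The algebraic identity MDD = 1.96 · (CV/100) · mean, usable directly
    on printed (mean, CV) summary pairs."""
    return 1.96 * (cv_pct / 100.0) * mean


def icc_category(icc: float) -> str:
    if icc < 0.40:
        return "poor"
    if icc < 0.60:
        return "fair"
    if icc < 0.75:
        return "good"
    return "excellent"


def icc_agreement_single(ratings: np.ndarray) -> tuple[float, str]:
    """ICC(A,1): two-way model, absolute agreement, single measures.

    ``ratings`` is an n_subjects × k_raters matrix (complete; no imputation).
    From the two-way ANOVA mean squares (rows = subjects, columns = raters):

        ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)
    """
    y = np.asarray(ratings, float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("need an n>=2 by k>=2 ratings matrix")
    if np.isnan(y).any():
        raise ValueError("ratings matrix is incomplete; no imputation is performed")
    n, k = y.shape
    grand = y.mean()
    row_m = y.mean(axis=1)
    col_m = y.mean(axis=0)
    ssr = k * np.sum((row_m - grand) ** 2)
    ssc = n * np.sum((col_m - grand) ** 2)
    sst = np.sum((y - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return float(icc), icc_category(float(icc))


def rl_percent_diff(right, left):
    """Right–left difference as a percentage of the bilateral mean:
    100·(R − L) / ((R + L)/2)."""
    r = np.asarray(right, float)
    l = np.asarray(left, float)
    denom = (r + l) / 2.0
    if np.any(denom == 0):
        raise ValueError("right+left is zero; percent difference undefined")
    return 100.0 * (r - l) / denom


# ---------------------------------------------------------------------------
# repeated-measures ANOVA with stepwise covariate entry


def _orthonormal_contrasts(p: int) -> np.ndarray:
    """(p, p-1) orthonormal contrast matrix (Helmert, normalised)."""
    c = np.zeros((p, p - 1))
    for j in range(1, p):
        c[:j, j - 1] = 1.0
        c[j, j - 1] = -j
        c[:, j - 1] /= np.linalg.norm(c[:, j - 1])
    return c


def _effect_contrasts(n_side: int = 2, n_root: int = 4) -> dict:
    """Contrast matrices over the side×root cell grid (cells ordered with
    root varying fastest within side)."""
    cs = _orthonormal_contrasts(n_side)
    cr = _orthonormal_contrasts(n_root)
    us = np.full((n_side, 1), 1.0 / np.sqrt(n_side))
    ur = np.full((n_root, 1), 1.0 / np.sqrt(n_root))
    return {
        "side": np.kron(cs, ur),
        "root": np.kron(us, cr),
        "side_x_root": np.kron(cs, cr),
    }


def _within_effect_test(Z: np.ndarray, X: np.ndarray) -> dict:
    """Univariate RM-ANOVA test that the population mean of the contrast
    scores Z (n × q_eff) is zero, adjusting for the between-subject design X
    (first column = intercept, covariates mean-centered)."""
    n, q_eff = Z.shape
    q = X.shape[1]
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Z
    resid = Z - X @ B
    E = resid.T @ resid
    df_e = n - q
    # hypothesis SSCP for the intercept (the within-effect grand mean)
    L = np.zeros((1, q))
    L[0, 0] = 1.0
    LB = L @ B
    H = LB.T @ np.linalg.inv(L @ XtX_inv @ L.T) @ LB
    ss_h, ss_e = np.trace(H), np.trace(E)
    df1 = q_eff
    df2 = q_eff * df_e
    F = (ss_h / df1) / (ss_e / df2)
    p = float(sps.f.sf(F, df1, df2))
    # sphericity diagnostics on the contrast-score covariance
    Sigma = E / df_e
    tr = np.trace(Sigma)
    eps = (tr**2) / (q_eff * np.trace(Sigma @ Sigma)) if q_eff > 1 else 1.0
    if q_eff > 1:
        detS = np.linalg.det(Sigma)
        W = detS / (tr / q_eff) ** q_eff if tr > 0 else np.nan
        if W > 0:
            chi2 = -(df_e - (2 * q_eff**2 + q_eff + 2) / (6.0 * q_eff)) * np.log(W)
            df_m = q_eff * (q_eff + 1) // 2 - 1
            mauchly_p = float(sps.chi2.sf(chi2, df_m))
        else:
            W, mauchly_p = float(W), 0.0
    else:
        W, mauchly_p = 1.0, 1.0
    p_gg = float(sps.f.sf(F, df1 * eps, df2 * eps))
    return {
        "F": float(F),
        "df1": df1,
        "df2": df2,
        "p": p,
        "epsilon": float(eps),
        "p_gg": p_gg,
        "mauchly_w": float(W),
        "mauchly_p": mauchly_p,
        # convention: GG correction applied when Mauchly rejects at 0.05
        "p_corrected": p_gg if mauchly_p < 0.05 else p,
    }


def _wide_cells(table: pd.DataFrame, metric: str) -> tuple[np.ndarray, list]:
    """Pivot a nerve-means table into an n_subjects × 8 cell matrix with
    cells ordered (right C5..C8, left C5..C8)."""
    roots = ["C5", "C6", "C7", "C8"]
    cells = [(s, r) for s in ("right", "left") for r in roots]
    piv = table.pivot_table(
        index="subject", columns=["side", "root"], values=metric, aggfunc="mean"
    )
    try:
        Y = np.column_stack([piv[c].to_numpy() for c in cells])
    except KeyError as e:
        raise ValueError(f"missing side/root cell in nerve-means table: {e}") from e
    if np.isnan(Y).any():
        raise ValueError("incomplete side×root data: every subject needs all 8 cells")
    return Y, list(piv.index)


def rm_anova(
    Y: np.ndarray,
    covariate_design: np.ndarray | None = None,
) -> dict:
    """Side / root / interaction tests on an n × 8 cell matrix (see
    ``_wide_cells`` for the ordering), optionally adjusted for mean-centered
    between-subject covariates."""
    Y = np.asarray(Y, float)
    n = len(Y)
    X = np.ones((n, 1))
    if covariate_design is not None:
        C = np.asarray(covariate_design, float)
        C = C - C.mean(axis=0, keepdims=True)
        X = np.column_stack([X, C])
    out = {}
    for name, M in _effect_contrasts().items():
        out[name] = _within_effect_test(Y @ M, X)
    return out


def _covariate_entry_p(u: np.ndarray, entered: np.ndarray, cand: np.ndarray) -> float:
    """Two-sided P of a candidate covariate's coefficient in an OLS of the
    subject-level means on [intercept, entered covariates, candidate]."""
    n = len(u)
    X = np.column_stack([np.ones(n), entered, cand]) if entered.size else np.column_stack(
        [np.ones(n), cand]
    )
    q = X.shape[1]
    beta, _, rank, _ = np.linalg.lstsq(X, u, rcond=None)
    if rank < q:
        return np.nan  # collinear with already-entered covariates
    resid = u - X @ beta
    df = n - q
    s2 = resid @ resid / df
    cov = s2 * np.linalg.inv(X.T @ X)
    t = beta[-1] / np.sqrt(cov[-1, -1])
    return float(2.0 * sps.t.sf(abs(t), df))


def rm_anova_stepwise(
    nerve_table: pd.DataFrame,
    covariates: pd.DataFrame,
    metric: str = "md",
    candidates: tuple = ("age", "sex", "bmi", "bsa_m2", "height_m", "weight_kg"),
    entry_p: float = 0.05,
) -> AnovaReport:
    """Repeated-measures ANOVA over the 2(side) × 4(root) within-subject
    layout with stepwise forward covariate selection.

    Candidates are tested one at a time on the between-subject component
    (subject means across the 8 cells); the smallest-P candidate below
    ``entry_p`` enters, and the search repeats among the rest until none
    qualifies.  This admits one representative of a correlated family (e.g.
    bodyweight rather than BMI) instead of forcing collinear covariates into
    the model together.  Candidates collinear with entered ones are reported
    with P = NaN, never silently dropped.  Side and root-level effects are
    then tested adjusted for the entered covariates; Greenhouse–Geisser
    corrected P values are used whenever Mauchly's test rejects sphericity.
    """
    Y, subjects = _wide_cells(nerve_table, metric)
    cov = covariates.set_index("subject").loc[subjects]
    missing = [c for c in candidates if c not in cov.columns]
    if missing:
        raise ValueError(f"covariate table lacks columns: {missing}")
    u = Y.mean(axis=1)
    pool = {c: cov[c].to_numpy(float) for c in candidates}
    for c in pool:
        pool[c] = pool[c] - pool[c].mean()
    entered: list[str] = []
    last_pvals: dict[str, float] = {}
    while True:
        remaining = [c for c in candidates if c not in entered]
        if not remaining:
            break
        Xe = (
            np.column_stack([pool[c] for c in entered]) if entered else np.empty((len(u), 0))
        )
        pvals = {c: _covariate_entry_p(u, Xe, pool[c]) for c in remaining}
        last_pvals = pvals
        finite = {c: p for c, p in pvals.items() if np.isfinite(p)}
        if not finite:
            break
        best = min(finite, key=finite.get)
        if finite[best] >= entry_p:
            break
        entered.append(best)
    design = np.column_stack([pool[c] for c in entered]) if entered else None
    effects = rm_anova(Y, design)
    return AnovaReport(
        effects=effects,
        selected_covariates=entered,
        covariate_p_values=last_pvals,
        n_subjects=len(Y),
    )


def linreg(x, y) -> RegressionResult:
    """Ordinary least squares of a metric on bodyweight (or any scalar
    predictor); two-sided P for the slope."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        slope_se=float(res.stderr),
    )


# ---------------------------------------------------------------------------
# report assembly


def _paired_from_table(
    table: pd.DataFrame, metric: str, pairing: str, root: str | None
) -> PairedSeries:
    col = {"session": "session", "rater": "rater"}[pairing]
    sub = table if root is None else table[table["root"] == root]
    levels = sorted(sub[col].unique())[:2]
    if len(levels) < 2:
        raise ValueError(f"pairing column '{col}' has fewer than 2 levels")
    keys = ["subject", "side", "root"]
    piv = sub[sub[col].isin(levels)].pivot_table(
        index=keys, columns=col, values=metric, aggfunc="mean"
    ).dropna()
    return PairedSeries(
        x1=piv[levels[0]].to_numpy(), x2=piv[levels[1]].to_numpy(), kind=pairing
    )


def repeatability_report(
    nerve_table: pd.DataFrame,
    pairing: str = "session",
    metrics: tuple = METRICS,
    roots: tuple = ("C5", "C6", "C7", "C8", None),
) -> pd.DataFrame:
    """Per-(root, metric) repeatability summary from a long nerve-means table.

    ``pairing='session'`` compares scan 1 vs scan 2 (within-subject);
    ``'rater'`` compares rater 1 vs rater 2.  ``root=None`` rows (labelled
    'Total') pool all roots.  Diffusivity columns are reported in
    ×10⁻³ mm²/s; the MDD ≡ 1.96·(CV/100)·mean identity holds exactly on the
    unrounded values.
    """
    rows = []
    for root in roots:
        for metric in metrics:
            pairs = _paired_from_table(nerve_table, metric, pairing, root)
            ba = bland_altman(pairs)
            scale = 1.0 if metric == "fa" else 1e3
            mat = np.column_stack([pairs.x1, pairs.x2])
            icc, cat = icc_agreement_single(mat)
            rows.append(
                {
                    "root": root if root is not None else "Total",
                    "metric": metric,
                    "n_pairs": len(pairs.x1),
                    "mean": pairs.grand_mean * scale,
                    "sd": np.concatenate([pairs.x1, pairs.x2]).std(ddof=1) * scale,
                    "cv_pct": cv_percent(pairs),
                    "mdd": mdd(pairs) * scale,
                    "ba_mean_diff": ba.mean_diff * scale,
                    "ba_lower": ba.lower * scale,
                    "ba_upper": ba.upper * scale,
                    "icc": icc,
                    "icc_category": cat,
                }
            )
    return pd.DataFrame(rows)


def load_supplementary_table(path, column_map: dict, sheet=0) -> pd.DataFrame:
    """Thin importer for per-subject summary spreadsheets (XLSX).

    ``column_map`` maps source column headers to this package's names
    (subject, weight_kg, fa, md, ad, rd, ...); unmapped columns are dropped.
    Raises if a mapped source column is absent — no silent guessing.
    """
    df = pd.read_excel(path, sheet_name=sheet)
    missing = [c for c in column_map if c not in df.columns]
    if missing:
        raise ValueError(f"spreadsheet lacks expected columns: {missing}")
    return df[list(column_map)].rename(columns=column_map)
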