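"""Group-level statistics: rm-ANOVA, t/Wilcoxon tests, stepwise regression,
permutation-corrected voxelwise group maps.

The repeated-measures ANOVA is the classical univariate (sphericity
assumed) mixed GLM: within-subject factors fully crossed and complete per
subject, one optional between-subject factor with possibly unequal group
sizes.  Each within effect is isolated by projecting every subject's
within-cell vector onto an orthonormal contrast basis; the pooled
between/within sums of squares of the projected scores give the familiar
F ratios (error term = effect x subject-within-group).  An optional
Greenhouse–Geisser correction is available.

The brain–behavior analysis is forward/backward stepwise regression with
partial-F entry at p < 0.05 and removal at p > 0.10.

Voxelwise group comparison uses an independent-samples t-map with
family-wise correction by permutation of group labels (max-|t| null) — a
self-contained, assumption-light analogue of parametric corrected
thresholds, and labelled as such in the output metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as ss

from .core import AnovaResult, BetaVolume, StepwiseResult
from .roi import smooth_volume

__all__ = [
    "rm_anova",
    "t_tests",
    "one_sample_wilcoxon",
    "stepwise_regression",
    "voxelwise_group_ttest",
    "VoxelwiseResult",
]


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA


def _orthonormal_contrast(n_levels: int) -> np.ndarray:
    """Orthonormal basis of the contrast space (columns sum to zero)."""
    m = np.eye(n_levels) - 1.0 / n_levels
    q, _ = np.linalg.qr(m)
    return q[:, : n_levels - 1]


def _complete_wide(
    table: pd.DataFrame, dv: str, within: Sequence[str], subject: str
) -> tuple[np.ndarray, list, pd.Index]:
    """Subjects x within-cells matrix in canonical cell order; errors on gaps."""
    levels = [sorted(table[w].unique()) for w in within]
    wide = table.pivot_table(
        index=subject, columns=list(within), values=dv, aggfunc="mean"
    )
    full_cols = (
        pd.MultiIndex.from_product(levels, names=list(within))
        if len(within) > 1
        else pd.Index(levels[0], name=within[0])
    )
    wide = wide.reindex(columns=full_cols)
    if wide.isna().any().any():
        missing = [
            (str(subj), tuple(np.atleast_1d(col)))
            for subj in wide.index
            for col in wide.columns[wide.loc[subj].isna()]
        ]
        raise ValueError(
            f"unbalanced design; missing cells (subject, cell): {missing[:10]}"
            + (" ..." if len(missing) > 10 else "")
        )
    return wide.to_numpy(dtype=float), levels, wide.index


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    within: Sequence[str],
    subject: str = "subject",
    between: Optional[str] = None,
    gg_correction: bool = False,
) -> list[AnovaResult]:
    """Mixed repeated-measures ANOVA on a tidy table.

    Returns F, degrees of freedom and p for every within effect, every
    within x between interaction, and the between main effect.  The design
    must be complete per subject (every within cell present); group sizes
    may differ.  ``gg_correction`` multiplies the dfs of each within effect
    by its Greenhouse–Geisser epsilon.
    """
    within = list(within)
    if not within:
        raise ValueError("need at least one within-subject factor")
    Y, levels, subjects = _complete_wide(table, dv, within, subject)
    n = Y.shape[0]
    if between is not None:
        per_subj = table.drop_duplicates(subject).set_index(subject)[between]
        group_labels = per_subj.reindex(subjects).to_numpy()
        if pd.isna(group_labels).any():
            raise ValueError("every subject needs a group label")
        group_names = sorted(pd.unique(group_labels))
    else:
        group_labels = np.array(["all"] * n)
        group_names = ["all"]
    g = len(group_names)
    if n <= g:
        raise ValueError("need more subjects than groups")
    group_idx = [np.flatnonzero(group_labels == name) for name in group_names]
    n_g = np.array([idx.size for idx in group_idx])

    results: list[AnovaResult] = []

    if between is not None:
        m_s = Y.mean(axis=1)
        mu_g = np.array([m_s[idx].mean() for idx in group_idx])
        grand = (n_g * mu_g).sum() / n
        ss_b = float((n_g * (mu_g - grand) ** 2).sum())
        ss_s = float(
            sum(((m_s[idx] - mu_g[i]) ** 2).sum() for i, idx in enumerate(group_idx))
        )
        df_b, df_s = g - 1, n - g
        results.append(_f_result(between, ss_b, df_b, ss_s, df_s))

    factor_sets = [
        [within[i] for i in range(len(within)) if mask & (1 << i)]
        for mask in range(1, 2 ** len(within))
    ]
    factor_sets.sort(key=len)
    for fset in factor_sets:
        mats = []
        for w, lv in zip(within, levels):
            if w in fset:
                mats.append(_orthonormal_contrast(len(lv)))
            else:
                mats.append(np.ones((len(lv), 1)) / np.sqrt(len(lv)))
        C = mats[0]
        for m in mats[1:]:
            C = np.kron(C, m)
        U = Y @ C  # (n, q)
        q = U.shape[1]
        mu = np.stack([U[idx].mean(axis=0) for idx in group_idx])  # (g, q)
        resid_ss = float(
            sum(((U[idx] - mu[i]) ** 2).sum() for i, idx in enumerate(group_idx))
        )
        df_err = q * (n - g)
        name = ":".join(fset)
        # main within effect: unweighted grand mean of group means (Type III)
        b0 = mu.mean(axis=0)
        h = g**2 / (1.0 / n_g).sum()
        ss_w = float(h * (b0**2).sum())
        eps = 1.0
        if gg_correction and q > 1:
            S = sum(
                (U[idx] - mu[i]).T @ (U[idx] - mu[i])
                for i, idx in enumerate(group_idx)
            ) / (n - g)
            tr = np.trace(S)
            denom = q * (S**2).sum()
            eps = float(tr**2 / denom) if denom > 0 else 1.0
            eps = min(1.0, max(eps, 1.0 / q))
        results.append(
            _f_result(name, ss_w, q * eps, resid_ss, df_err * eps)
        )
        if between is not None:
            wbar = (n_g[:, None] * mu).sum(axis=0) / n
            ss_int = float((n_g[:, None] * (mu - wbar) ** 2).sum())
            results.append(
                _f_result(
                    f"{between}:{name}",
                    ss_int,
                    q * (g - 1) * eps,
                    resid_ss,
                    df_err * eps,
                )
            )
    return results


def _f_result(
    name: str, ss_num: float, df_num: float, ss_den: float, df_den: float
) -> AnovaResult:
    if ss_den <= 0 or df_den <= 0:
        warnings.warn(f"zero error variance for effect '{name}'; F set to 0")
        return AnovaResult(name, 0.0, df_num, df_den, 1.0, ss_num, ss_den)
    F = (ss_num / df_num) / (ss_den / df_den)
    p = float(ss.f.sf(F, df_num, df_den))
    return AnovaResult(name, float(F), df_num, df_den, p, ss_num, ss_den)


# ---------------------------------------------------------------------------
# t tests and Wilcoxon


def t_tests(
    a: np.ndarray,
    b: Optional[np.ndarray] = None,
    paired: bool = False,
    mu: float = 0.0,
) -> tuple[float, float, float]:
    """Student t statistics with complete-case missing-value handling.

    One-sample against ``mu`` when ``b`` is None; otherwise paired
    (pairwise-complete) or independent (per-sample complete) two-sample.
    Returns (t, df, p).
    """
    a = np.asarray(a, dtype=float)
    if b is None:
        a = a[~np.isnan(a)]
        if a.size < 2:
            raise ValueError("need at least 2 non-missing values")
        res = ss.ttest_1samp(a, mu)
        return float(res.statistic), float(a.size - 1), float(res.pvalue)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired samples must have equal length")
        keep = ~(np.isnan(a) | np.isnan(b))
        a, b = a[keep], b[keep]
        if a.size < 2:
            raise ValueError("fewer than 2 complete pairs")
        d = a - b
        if d.std(ddof=1) == 0:  # identical pairs: no evidence of difference
            t = 0.0 if d[0] == 0 else float(np.sign(d[0]) * np.inf)
            return t, float(a.size - 1), 1.0 if t == 0.0 else 0.0
        res = ss.ttest_rel(a, b)
        return float(res.statistic), float(a.size - 1), float(res.pvalue)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 non-missing values per sample")
    res = ss.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(a.size + b.size - 2), float(res.pvalue)


def one_sample_wilcoxon(
    x: np.ndarray, mu: float, zero_method: str = "wilcox"
) -> tuple[float, float]:
    """One-sample Wilcoxon signed-rank test of ``x`` against ``mu``.

    Default zero handling drops exact ties with ``mu`` (classic signed
    rank) and uses the exact null for n <= 25, a continuity-corrected
    normal approximation above.  ``zero_method="pratt"`` keeps zeros in the
    ranking (closer to some statistics packages' one-sample variant, which
    matters when many observations sit exactly at a scale ceiling).
    Returns (W, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    d = x[~np.isnan(x)] - mu
    if d.size == 0:
        raise ValueError("no non-missing observations")
    nonzero = np.count_nonzero(d)
    if nonzero == 0:
        raise ValueError("all differences are zero; test undefined")
    if zero_method == "wilcox":
        method = "exact" if nonzero <= 25 else "approx"
    else:
        method = "approx"
    res = ss.wilcoxon(
        d, zero_method=zero_method, correction=(method == "approx"), method=method
    )
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Stepwise brain-behavior regression


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def _partial_f_p(
    base: np.ndarray, candidate: np.ndarray, y: np.ndarray
) -> float:
    """p-value of the F test for adding one column to an OLS model."""
    n = y.size
    full = np.column_stack([base, candidate])
    p_full = full.shape[1]
    df2 = n - p_full
    if df2 <= 0:
        return 1.0
    rss0 = _ols_rss(base, y)
    rss1 = _ols_rss(full, y)
    if rss1 <= 0:
        return 0.0
    F = (rss0 - rss1) / (rss1 / df2)
    return float(ss.f.sf(max(F, 0.0), 1, df2))


def stepwise_regression(
    predictors: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    p_in: float = 0.05,
    p_out: float = 0.10,
    cond_threshold: float = 1e8,
    max_steps: int = 100,
) -> StepwiseResult:
    """Forward/backward stepwise OLS with partial-F entry and removal.

    At each step the not-yet-included candidate with the smallest
    partial-F p enters if p < ``p_in`` (ties broken by lowest column
    index); afterwards any included factor whose drop-one p exceeds
    ``p_out`` is removed, worst first.  Candidates that would make the
    design numerically collinear are skipped with a warning.  Iterates to a
    fixed point; deterministic throughout.
    """
    if isinstance(predictors, pd.DataFrame):
        names = list(predictors.columns)
        X = predictors.to_numpy(dtype=float)
    else:
        X = np.asarray(predictors, dtype=float)
        names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(X).any(axis=1))
    X, y = X[keep], y[keep]
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 complete observations")
    result = StepwiseResult()
    model: list[int] = []
    if np.var(y) == 0:
        warnings.warn("outcome has zero variance; returning the empty model")
        result.intercept = float(y.mean()) if n else float("nan")
        result.r_squared = 0.0
        return result

    def design(cols):
        return np.column_stack([np.ones(n)] + [X[:, j] for j in cols])

    for _ in range(max_steps):
        changed = False
        # forward entry
        base = design(model)
        if n > len(model) + 3:
            best_j, best_p = None, np.inf
            for j in range(X.shape[1]):
                if j in model:
                    continue
                cand = np.column_stack([base, X[:, j]])
                if np.linalg.cond(cand) > cond_threshold:
                    warnings.warn(
                        f"candidate '{names[j]}' is collinear with the model; skipped"
                    )
                    continue
                p = _partial_f_p(base, X[:, j], y)
                if p < best_p:  # strict: ties keep the lowest index
                    best_j, best_p = j, p
            if best_j is not None and best_p < p_in:
                model.append(best_j)
                result.steps.append(("enter", names[best_j], best_p))
                changed = True
        # backward removal
        while len(model) > 0:
            ps = []
            for j in model:
                others = [k for k in model if k != j]
                p = _partial_f_p(design(others), X[:, j], y)
                ps.append(p)
            worst = int(np.argmax(ps))
            if ps[worst] > p_out:
                removed = model.pop(worst)
                result.steps.append(("remove", names[removed], ps[worst]))
                changed = True
            else:
                break
        if not changed:
            break

    result.selected = [names[j] for j in model]
    if model:
        D = design(model)
        coef, *_ = np.linalg.lstsq(D, y, rcond=None)
        result.intercept = float(coef[0])
        result.coefficients = {
            names[j]: float(c) for j, c in zip(model, coef[1:])
        }
        result.pvalues = {
            names[j]: _partial_f_p(design([k for k in model if k != j]), X[:, j], y)
            for j in model
        }
        rss = _ols_rss(D, y)
        tss = float(((y - y.mean()) ** 2).sum())
        result.r_squared = 1.0 - rss / tss if tss > 0 else float("nan")
    else:
        result.intercept = float(y.mean())
        result.r_squared = 0.0
    return result


# ---------------------------------------------------------------------------
# Voxelwise group comparison


@dataclass
class VoxelwiseResult:
    tmap: np.ndarray
    threshold: float
    sig_mask: np.ndarray
    null_max: np.ndarray
    metadata: dict = field(default_factory=dict)


def _two_sample_tmap(data: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per voxel; zero-variance voxels get t=0."""
    a, b = data[is_a], data[~is_a]
    n1, n2 = a.shape[0], b.shape[0]
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1 = a.var(axis=0, ddof=1)
    v2 = b.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m1 - m2) / denom, 0.0)
    return t


def voxelwise_group_ttest(
    volumes: Sequence[BetaVolume],
    groups: Sequence[str],
    fwhm_mm: float = 8.0,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> VoxelwiseResult:
    """Voxelwise two-sample t-map with permutation max-|t| FWE correction.

    Each volume is Gaussian-smoothed (default 8 mm FWHM), a pooled-variance
    t statistic is computed per voxel, and the family-wise threshold is the
    (1 - alpha) quantile of the max-|t| distribution over ``n_perm`` random
    relabelings of the groups (the identity labeling is included in the
    null, making the threshold slightly conservative).
    """
    groups = np.asarray(groups)
    names = sorted(pd.unique(groups))
    if len(names) != 2:
        raise ValueError("exactly two groups required")
    is_a = groups == names[0]
    if is_a.sum() < 2 or (~is_a).sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    shapes = {v.data.shape for v in volumes}
    if len(shapes) != 1:
        raise ValueError(f"volumes are not on a common grid: {shapes}")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; corrected threshold is unstable")
    smoothed = [smooth_volume(v, fwhm_mm) for v in volumes]
    data = np.stack([v.data.reshape(-1) for v in smoothed])
    tmap = _two_sample_tmap(data, is_a)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm + 1)
    null[0] = np.abs(tmap).max()
    for i in range(n_perm):
        perm = rng.permutation(is_a)
        null[i + 1] = np.abs(_two_sample_tmap(data, perm)).max()
    threshold = float(np.quantile(null, 1.0 - alpha))
    shape = volumes[0].data.shape
    return VoxelwiseResult(
        tmap=tmap.reshape(shape),
        threshold=threshold,
        sig_mask=(np.abs(tmap) > threshold).reshape(shape),
        null_max=null,
        metadata={
            "correction": "permutation max-|t| family-wise",
            "fwhm_mm": fwhm_mm,
            "n_perm": n_perm,
            "alpha": alpha,
            "seed": seed,
            "groups": list(names),
        },
    )
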