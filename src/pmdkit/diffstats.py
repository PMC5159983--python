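"""Group-comparison and covariate statistics for methylome features.

Feature-level differential methylation uses Welch's unequal-variance t-test
(the conservative default when only "a t test" is specified) with
Benjamini-Hochberg FDR control at 5% applied within each feature class —
domains, chromosomes, promoters, CpG islands, gene bodies, 20 kb windows and
chromatin-state elements are each their own testing family.  Covariate
analyses are ordinary least squares on unit-scaled responses, with AIC model
selection and heteroscedasticity-consistent (HC1) sandwich confidence
intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CpGTrack, ValidationError

FEATURE_CLASSES = (
    "PMD", "HMD", "chromosome", "promoter", "CGI", "gene_body",
    "window20kb", "chromhmm_state_element",
)


# ---------------------------------------------------------------------------
# Welch t-test
# ---------------------------------------------------------------------------

def _welch_arrays(a: np.ndarray, b: np.ndarray):
    """Vectorised Welch t over the last axis of two 2-D arrays (NaN-aware)."""
    na = np.sum(~np.isnan(a), axis=-1)
    nb = np.sum(~np.isnan(b), axis=-1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows are filtered later
        ma = np.nanmean(a, axis=-1)
        mb = np.nanmean(b, axis=-1)
        va = np.nanvar(a, axis=-1, ddof=1)
        vb = np.nanvar(b, axis=-1, ddof=1)
    sa, sb = va / na, vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(sa + sb)
        df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, df, p, ma, mb, va, vb, na, nb


def welch_ttest(a, b, pooled_variance: bool = False):
    """Two-sided t-test for the difference in group means.

    By default the Welch unequal-variance statistic with Welch-Satterthwaite
    degrees of freedom; set ``pooled_variance=True`` for the classical
    equal-variance Student test.

    Degenerate inputs follow explicit conventions: if both groups have zero
    variance, p = 1 when the means are equal and p = 0 (t = +/-inf) when they
    differ.

    Returns ``(t, df, p)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs >=2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), float(a.size + b.size - 2), 0.0
    if pooled_variance:
        t, p = stats.ttest_ind(a, b, equal_var=True)
        return float(t), float(a.size + b.size - 2), float(p)
    t, df, p, *_ = _welch_arrays(a[None, :], b[None, :])
    return float(t[0]), float(df[0]), float(p[0])


# ---------------------------------------------------------------------------
# Benjamini-Hochberg FDR
# ---------------------------------------------------------------------------

def bh_fdr(pvalues, alpha: float = 0.05):
    """Benjamini-Hochberg step-up q-values and the rejection set.

    Returns ``(q, rejected)`` with ``rejected = (q <= alpha)``; q-values are
    the monotone-adjusted step-up values, so the rejection set equals the
    classical largest-i rule at level ``alpha``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    rejected, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, rejected


# ---------------------------------------------------------------------------
# Feature scan
# ---------------------------------------------------------------------------

@dataclass
class FeatureStatTable:
    """Per-feature Welch tests with BH-FDR within one feature class."""

    data: pd.DataFrame
    feature_class: str
    alpha: float
    n_skipped: int

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.data.sort_values(["q", "p"], kind="mergesort").head(n)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def feature_scan(
    values: pd.DataFrame,
    groups: Mapping[str, str],
    feature_class: str,
    group_a: str = "ASD",
    group_b: str = "TD",
    alpha: float = 0.05,
) -> FeatureStatTable:
    """Welch-test every feature between two groups, BH-correct within class.

    ``values`` is features x samples (NaN = missing).  Features with fewer
    than two non-missing values in either group, or zero variance in both,
    are skipped and counted rather than assigned a degenerate p-value.
    BH-FDR runs over the tested features of this class only: each feature
    class forms its own multiple-testing family.
    """
    if feature_class not in FEATURE_CLASSES:
        raise ValidationError(f"unknown feature class {feature_class!r}")
    cols_a = [s for s in values.columns if groups.get(s) == group_a]
    cols_b = [s for s in values.columns if groups.get(s) == group_b]
    if not cols_a or not cols_b:
        raise ValidationError("both groups must be represented among the samples")
    a = values[cols_a].to_numpy(dtype=float)
    b = values[cols_b].to_numpy(dtype=float)
    t, df, p, ma, mb, va, vb, na, nb = _welch_arrays(a, b)
    testable = (na >= 2) & (nb >= 2) & ((va > 0) | (vb > 0))
    n_skipped = int((~testable).sum())
    out = pd.DataFrame(
        {
            "feature_id": values.index.to_numpy()[testable],
            "feature_class": feature_class,
            f"mean_{group_a}": ma[testable],
            f"mean_{group_b}": mb[testable],
            "t": t[testable],
            "df": df[testable],
            "p": p[testable],
        }
    )
    q, rejected = bh_fdr(out["p"].to_numpy(), alpha=alpha)
    out["q"] = q
    out["rejected"] = rejected
    return FeatureStatTable(out, feature_class, alpha, n_skipped)


# ---------------------------------------------------------------------------
# Chromatin-state profiles
# ---------------------------------------------------------------------------

def chromstate_profile(
    tracks: Sequence[CpGTrack],
    elements: pd.DataFrame,
    groups: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average methylation per chromatin-state element and per state.

    For each element the per-sample value is the unweighted mean of per-CpG
    fractions inside the element (not count-pooled — each CpG site counts
    once), then element values are averaged across the samples of each
    group.  State-level rows summarise the element distribution per group
    with median, quartiles and whiskers at the furthest points within 1.5x
    the interquartile range, the usual box-plot convention.

    Returns ``(element_table, state_summary)``.
    """
    elements = pd.DataFrame(elements).reset_index(drop=True)
    label_col = "state" if "state" in elements.columns else "name"
    per_sample = {}
    for track in tracks:
        vals = np.full(len(elements), np.nan)
        df = track.data
        frac_all = df["meth"].to_numpy() / df["total"].to_numpy()
        for chrom, grp_idx in df.groupby("chrom", sort=False).groups.items():
            sel = elements["chrom"] == chrom
            if not sel.any():
                continue
            pos = df.loc[grp_idx, "pos"].to_numpy()
            fr = frac_all[df.index.get_indexer(grp_idx)]
            for i in np.flatnonzero(sel.to_numpy()):
                s, e = elements.at[i, "start"], elements.at[i, "end"]
                lo, hi = np.searchsorted(pos, [s, e])
                if hi > lo:
                    vals[i] = fr[lo:hi].mean()
        per_sample[track.sample_id] = vals
    mat = pd.DataFrame(per_sample)
    element_table = elements[["chrom", "start", "end", label_col]].rename(columns={label_col: "state"}).copy()
    if groups:
        for g in sorted(set(groups.values())):
            cols = [s for s in mat.columns if groups.get(s) == g]
            element_table[f"mean_{g}"] = mat[cols].mean(axis=1) if cols else np.nan
    else:
        element_table["mean_all"] = mat.mean(axis=1)
    value_cols = [c for c in element_table.columns if c.startswith("mean_")]
    rows = []
    for state, grp in element_table.groupby("state", sort=True):
        for col in value_cols:
            v = grp[col].dropna().to_numpy()
            if v.size == 0:
                continue
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            iqr = q3 - q1
            lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            inside = v[(v >= lo_fence) & (v <= hi_fence)]
            rows.append((state, col.removeprefix("mean_"), v.size, med, q1, q3,
                         inside.min(), inside.max()))
    state_summary = pd.DataFrame(
        rows, columns=["state", "group", "n_elements", "median", "q1", "q3",
                       "whisker_low", "whisker_high"],
    )
    return element_table, state_summary


# ---------------------------------------------------------------------------
# Regressions
# ---------------------------------------------------------------------------

def _design(predictors: pd.DataFrame, references: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Numeric design matrix: categoricals become treatment-coded dummies
    against a declared (or first-sorted) reference level."""
    references = references or {}
    cols = {}
    for name in predictors.columns:
        col = predictors[name]
        if pd.api.types.is_numeric_dtype(col):
            cols[name] = col.astype(float)
        else:
            levels = sorted(col.dropna().unique())
            ref = references.get(name, levels[0])
            if ref not in levels:
                raise ValidationError(f"reference level {ref!r} absent from {name!r}")
            for lev in levels:
                if lev != ref:
                    cols[f"{name}[{lev}]"] = (col == lev).astype(float)
    return pd.DataFrame(cols, index=predictors.index)


def _check_full_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X.to_numpy())
        bad = [X.columns[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-10]
        raise ValidationError(f"rank-deficient design; collinear columns: {bad}")


def univariate_regressions(
    responses: pd.DataFrame,
    predictors: pd.DataFrame,
    units: Mapping[str, float] | None = None,
    adjust: Mapping[str, str] | None = None,
    references: Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Unit-scaled univariate OLS of each response on each predictor.

    ``units`` maps a response name to its unit of change (e.g. 0.05 for
    "per 5 percentage points"); the response is divided by the unit so every
    coefficient reads "units of response per unit of predictor".  ``adjust``
    maps a response to a co-response included as an extra covariate (e.g.
    PMD mean adjusted for HMD mean).  Categorical predictors are
    treatment-coded against ``references`` (sorted-first by default; declare
    e.g. ``{"race_ethnicity": "white non-Hispanic", "sex": "M"}`` to match a
    study's reference levels).  BH-FDR is applied across the whole family of
    reported terms.

    Returns one row per (response, predictor, term) with classical and HC1
    sandwich-robust 95% confidence intervals.
    """
    units = units or {}
    adjust = adjust or {}
    rows = []
    for resp in responses.columns:
        unit = float(units.get(resp, 1.0))
        y_all = responses[resp].astype(float) / unit
        extra = adjust.get(resp)
        for pred in predictors.columns:
            X = _design(predictors[[pred]], references)
            if extra is not None:
                X = X.assign(**{extra: responses[extra].astype(float)})
            keep = y_all.notna() & X.notna().all(axis=1)
            if int(keep.sum()) < 3:
                raise ValidationError(f"{resp} ~ {pred}: need >=3 complete samples")
            Xk = sm.add_constant(X[keep], has_constant="add")
            _check_full_rank(Xk)
            fit = sm.OLS(y_all[keep], Xk).fit()
            robust = fit.get_robustcov_results(cov_type="HC1")
            ci = fit.conf_int(alpha=0.05)
            rci = pd.DataFrame(robust.conf_int(alpha=0.05), index=Xk.columns)
            for term in X.columns:
                if extra is not None and term == extra:
                    continue  # the adjustment covariate is not itself a tested term
                rows.append({
                    "response": resp,
                    "predictor": pred,
                    "term": term,
                    "adjusted_for": extra,
                    "unit": unit,
                    "coef": fit.params[term],
                    "se": fit.bse[term],
                    "ci_low": ci.loc[term, 0],
                    "ci_high": ci.loc[term, 1],
                    "robust_ci_low": rci.loc[term, 0],
                    "robust_ci_high": rci.loc[term, 1],
                    "p": fit.pvalues[term],
                    "n": int(keep.sum()),
                })
    report = pd.DataFrame(rows)
    q, rejected = bh_fdr(report["p"].to_numpy(), alpha=alpha)
    report["q"] = q
    report["rejected"] = rejected
    return report


@dataclass
class ModelSelection:
    """AIC comparison of candidate OLS models with robust CIs for the winner."""

    table: pd.DataFrame                  # model, n_params, aic, selected
    selected: str
    coefficients: pd.DataFrame           # term, coef, robust_se, ci_low, ci_high, p
    tie_broken: bool = False
    notes: list = field(default_factory=list)

    def summary(self) -> str:
        lines = [f"AIC model selection — selected: {self.selected}"]
        for row in self.table.itertuples(index=False):
            mark = "*" if row.selected else " "
            lines.append(f" {mark} {row.model:<24s} k={row.n_params:<3d} AIC={row.aic:.3f}")
        lines.append("Selected-model coefficients (HC1 robust 95% CI):")
        for row in self.coefficients.itertuples(index=False):
            lines.append(
                f"   {row.term:<24s} {row.coef:+.4f}  [{row.ci_low:+.4f}, {row.ci_high:+.4f}]  p={row.p:.3g}"
            )
        return "\n".join(lines)


def model_select_robust(
    response: pd.Series,
    candidates: Mapping[str, pd.DataFrame],
    references: Mapping[str, str] | None = None,
    aicc: bool = False,
) -> ModelSelection:
    """Select the most parsimonious candidate model by AIC.

    Every candidate is OLS of ``response`` on its covariate frame (plus a
    constant); the AIC uses the Gaussian log-likelihood with the constant
    counted among the parameters.  All candidates must resolve to the same
    complete-case sample set, otherwise AICs are not comparable and an error
    is raised.  Ties go to the model with fewer parameters, then to the
    first declared.  The winner's coefficients get HC1 sandwich-robust 95%
    confidence intervals.  ``aicc=True`` applies the small-sample correction.
    """
    y = pd.Series(response).astype(float)
    fits, rows = {}, []
    common_index = None
    for name, covs in candidates.items():
        X = _design(pd.DataFrame(covs, index=y.index), references)
        keep = y.notna() & (X.notna().all(axis=1) if len(X.columns) else y.notna())
        idx = frozenset(y.index[keep])
        if common_index is None:
            common_index = idx
        elif idx != common_index:
            raise ValidationError(
                f"candidate {name!r} fits on a different sample subset; AICs not comparable"
            )
        Xk = sm.add_constant(X[keep], has_constant="add")
        _check_full_rank(Xk)
        fit = sm.OLS(y[keep], Xk).fit()
        k = Xk.shape[1]
        aic = fit.aic
        if aicc:
            n = int(keep.sum())
            aic = aic + 2 * k * (k + 1) / (n - k - 1)
        fits[name] = fit
        rows.append({"model": name, "n_params": k, "aic": float(aic)})
    table = pd.DataFrame(rows)
    order = table.sort_values(["aic", "n_params"], kind="mergesort")
    selected = str(order.iloc[0]["model"])
    best = order.iloc[0]
    tie = bool(((table["aic"] == best["aic"]) & (table["n_params"] == best["n_params"])).sum() > 1)
    table["selected"] = table["model"] == selected
    fit = fits[selected]
    robust = fit.get_robustcov_results(cov_type="HC1")
    rci = np.atleast_2d(robust.conf_int(alpha=0.05))
    coef = pd.DataFrame({
        "term": fit.params.index,
        "coef": fit.params.to_numpy(),
        "robust_se": np.atleast_1d(robust.bse),
        "ci_low": rci[:, 0],
        "ci_high": rci[:, 1],
        "p": np.atleast_1d(robust.pvalues),
    })
    notes = ["tie broken toward fewer parameters, then declaration order"] if tie else []
    return ModelSelection(table, selected, coef, tie_broken=tie, notes=notes)
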