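"""Log-linear modeling of gene expression on affinity profiles.

The model is

    e_g = sum_i c_i * a_g(i) + b + r_g

where e_g is log2 expression of gene g, a_g(i) the TBA (or occupancy) of
gene g's regulatory region for PWM i, c_i the per-PWM coefficient, b the
intercept and r_g the residual.  Fits are ordinary least squares; quality is
reported as adjusted R-squared with the whole-model F-test p-value against an
intercept-only model.  Companion procedures quantify overfitting (10-fold
cross-validation), regressor redundancy (lasso with CV-minimizing penalty)
and specificity (column-shuffled PWMs, base/CpG-composition baseline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from affinityscan.affinity import ScoreMatrix, SequenceRecord, score_matrix
from affinityscan.pwm import BASE_INDEX, PWM, Background, shuffle_pwm


@dataclass
class ModelFit:
    """An OLS fit of expression on an affinity design matrix."""

    coefficients: pd.Series
    intercept: float
    r2: float
    adj_r2: float
    p_value: float
    residuals: pd.Series
    n_genes: int
    n_predictors: int
    coef_p_values: pd.Series | None = None

    def summary_dict(self) -> dict:
        return {
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "p_value": self.p_value,
            "n_genes": self.n_genes,
            "n_predictors": self.n_predictors,
        }


@dataclass
class LassoFit:
    """An L1-penalized fit with CV-selected penalty; coefficients on the original scale."""

    coefficients: pd.Series
    intercept: float
    selected: list[str]
    penalty: float
    cv_r2: float
    n_genes: int


def normalize_expression(table: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """log2-transform raw expression after adding a per-column pseudo-count.

    The pseudo-count is the smallest non-zero value of that column, so zero
    expression maps to the log of the detection floor rather than -inf.
    Strictly monotone in the raw values, hence rank-preserving.
    """
    if isinstance(table, pd.Series):
        return normalize_expression(table.to_frame())[table.name or 0]

    out = {}
    for col in table.columns:
        raw = table[col].astype(float)
        if (raw < 0).any():
            raise ValueError(f"column {col!r}: negative expression values")
        positive = raw[raw > 0]
        if positive.empty:
            raise ValueError(f"column {col!r}: all expression values are zero")
        out[col] = np.log2(raw + positive.min())
    return pd.DataFrame(out, index=table.index)


def _align(design: ScoreMatrix | pd.DataFrame, expr: pd.Series) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Align genes between design and expression, dropping unscorable genes."""
    X = design.values if isinstance(design, ScoreMatrix) else design
    common = X.index.intersection(expr.index)
    X = X.loc[common]
    y = expr.loc[common].astype(float)
    bad = X.index[X.isna().any(axis=1) | ~np.isfinite(X).all(axis=1) | y.isna()]
    dropped = list(bad)
    keep = X.index.difference(bad, sort=False)
    return X.loc[keep], y.loc[keep], dropped


def fit_linear(design: ScoreMatrix | pd.DataFrame, expr: pd.Series) -> ModelFit:
    """OLS of expression on the affinity design matrix, plus an intercept.

    Genes with any missing (NaN) or non-finite score are dropped and listed in
    the error message only when nothing usable remains; a rank-deficient
    design raises with the names of the collinear columns.
    """
    X, y, _dropped = _align(design, expr)
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError(f"need more genes ({X.shape[0]}) than predictors ({X.shape[1]})")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.to_numpy()]))
    if rank < X.shape[1] + 1:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.max().sort_values(ascending=False)
        suspects = list(worst.index[worst > 0.999999]) or list(X.columns[X.std() == 0])
        raise ValueError(f"design matrix is rank-deficient; collinear/constant columns: {suspects}")
    model = sm.OLS(y.to_numpy(), sm.add_constant(X.to_numpy())).fit()
    return ModelFit(
        coefficients=pd.Series(model.params[1:], index=X.columns, name="coefficient"),
        intercept=float(model.params[0]),
        r2=float(model.rsquared),
        adj_r2=float(model.rsquared_adj),
        p_value=float(model.f_pvalue),
        residuals=pd.Series(model.resid, index=X.index, name="residual"),
        n_genes=int(model.nobs),
        n_predictors=X.shape[1],
        coef_p_values=pd.Series(model.pvalues[1:], index=X.columns, name="p"),
    )


def crossval_r2(design: ScoreMatrix | pd.DataFrame, expr: pd.Series, folds: int = 10, seed: int = 0) -> float:
    """Mean held-out R-squared over k shuffled folds of the genes."""
    X, y, _ = _align(design, expr)
    n = len(X)
    if folds > n:
        raise ValueError(f"cannot make {folds} folds from {n} genes")
    Xa, ya = X.to_numpy(), y.to_numpy()
    r2s = []
    for train, test in KFold(n_splits=folds, shuffle=True, random_state=seed).split(Xa):
        model = sm.OLS(ya[train], sm.add_constant(Xa[train])).fit()
        pred = sm.add_constant(Xa[test], has_constant="add") @ model.params
        resid = ya[test] - pred
        r2s.append(1.0 - resid @ resid / ((ya[test] - ya[test].mean()) @ (ya[test] - ya[test].mean())))
    return float(np.mean(r2s))


def fit_lasso(design: ScoreMatrix | pd.DataFrame, expr: pd.Series, seed: int = 0, folds: int = 10) -> LassoFit:
    """Lasso with the penalty minimizing 10-fold cross-validation error.

    Predictors are standardized internally; coefficients are mapped back to
    the original scale.  The selected PWM set is the nonzero-coefficient set.
    """
    X, y, _ = _align(design, expr)
    Xa, ya = X.to_numpy(), y.to_numpy()
    mu, sigma = Xa.mean(axis=0), Xa.std(axis=0)
    sigma[sigma == 0] = 1.0
    Xs = (Xa - mu) / sigma
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    model = LassoCV(cv=cv, alphas=100, max_iter=50000, random_state=seed).fit(Xs, ya)
    coef = model.coef_ / sigma
    intercept = float(model.intercept_ - (model.coef_ * mu / sigma).sum())
    # held-out R2 at the chosen penalty, from the stored CV mean squared error
    mse = model.mse_path_[model.alphas_ == model.alpha_].mean()
    cv_r2 = float(1.0 - mse / ya.var())
    coefficients = pd.Series(coef, index=X.columns, name="coefficient")
    return LassoFit(
        coefficients=coefficients,
        intercept=intercept,
        selected=list(coefficients.index[coefficients != 0]),
        penalty=float(model.alpha_),
        cv_r2=cv_r2,
        n_genes=len(X),
    )


def shuffled_pwm_control(
    pwms: list[PWM],
    seqs: list[SequenceRecord],
    expr: pd.DataFrame | pd.Series,
    bg: Background | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Compare model fit with real PWMs vs column-shuffled PWMs.

    Expression may carry several columns (cell lines); each is fitted against
    the real-PWM TBA design and against a design built from shuffled PWMs
    (positions permuted, base composition kept).  Returns the paired
    adjusted-R2 table and a paired Wilcoxon p-value across columns (NaN when
    only one column is supplied).
    """
    if isinstance(expr, pd.Series):
        expr = expr.to_frame(expr.name or "expression")
    rng = np.random.default_rng(seed)
    shuffled = [shuffle_pwm(p, int(rng.integers(2**31))) for p in pwms]
    design_real = score_matrix(pwms, seqs, bg, mode="tba")
    design_shuf = score_matrix(shuffled, seqs, bg, mode="tba")
    rows = []
    for col in expr.columns:
        fit_real = fit_linear(design_real, expr[col])
        fit_shuf = fit_linear(design_shuf, expr[col])
        rows.append({"cell_line": col, "adj_r2_real": fit_real.adj_r2, "adj_r2_shuffled": fit_shuf.adj_r2})
    table = pd.DataFrame(rows).set_index("cell_line")
    deltas = (table["adj_r2_real"] - table["adj_r2_shuffled"]).to_numpy()
    if len(deltas) < 2 or np.all(deltas == 0):
        p = float("nan") if len(deltas) < 2 else 1.0
    else:
        p = float(stats.wilcoxon(deltas, alternative="two-sided").pvalue)
    return table, p


def composition_features(seqs: list[SequenceRecord]) -> pd.DataFrame:
    """Per-sequence base frequencies (A, C, G; T is redundant) plus CpG frequency.

    CpG frequency is the count of CG dinucleotides over the number of
    dinucleotide positions (length - 1).
    """
    rows = []
    for s in seqs:
        seq = s.bases.upper()
        n = sum(seq.count(b) for b in BASE_INDEX)
        freqs = {f"freq_{b}": (seq.count(b) / n if n else np.nan) for b in "ACG"}
        cpg = seq.count("CG") / (len(seq) - 1) if len(seq) > 1 else 0.0
        rows.append({"sequence_id": s.id, **freqs, "freq_CpG": cpg})
    return pd.DataFrame(rows).set_index("sequence_id")


def composition_baseline(seqs: list[SequenceRecord], expr: pd.Series) -> ModelFit:
    """OLS of expression on base composition and CpG frequency alone.

    A motif-free baseline: how much of expression is explained by generic
    sequence composition rather than positional motif structure.
    """
    return fit_linear(composition_features(seqs), expr)
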