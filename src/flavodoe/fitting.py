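"""OLS polynomial fitting, ANOVA with lack-of-fit, and Pareto effects.

Fits first-order (screening) and second-order (response-surface) models in
coded units,

    Y = b0 + sum_i bi Xi                                   (order 1)
    Y = b0 + sum_i bi Xi + sum_{i<j} bij Xi Xj + sum_i bii Xi^2   (order 2)

and reproduces the standard design-of-experiments ANOVA: partial
(Type III) single-degree-of-freedom term sums of squares, an F test per
term, a lack-of-fit / pure-error split from replicated runs, and the usual
fit statistics (R2, adjusted R2, predicted R2 via PRESS, CV%, adequate
precision). Standardized effects |t| = |b|/se(b) with t and Bonferroni
significance limits support Pareto screening charts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .designs import DesignMatrix

__all__ = [
    "PolyModel",
    "AnovaTable",
    "ParetoEffects",
    "term_labels",
    "build_model_matrix",
    "fit_model",
    "anova",
    "fit_statistics",
    "pareto_effects",
]

log = logging.getLogger(__name__)


def term_labels(factor_names, order: int) -> list[str]:
    """Model term labels in table order: intercept, linear, interactions, quadratics."""
    names = list(factor_names)
    labels = ["Intercept"] + names
    if order == 2:
        k = len(names)
        labels += [f"{names[i]}:{names[j]}" for i in range(k) for j in range(i + 1, k)]
        labels += [f"{n}^2" for n in names]
    elif order != 1:
        raise ValueError("order must be 1 or 2")
    return labels


def build_model_matrix(levels: np.ndarray, order: int) -> np.ndarray:
    """Columns of the polynomial basis evaluated at coded design rows."""
    X = np.atleast_2d(np.asarray(levels, dtype=float))
    n, k = X.shape
    cols = [np.ones(n)] + [X[:, i] for i in range(k)]
    if order == 2:
        cols += [X[:, i] * X[:, j] for i in range(k) for j in range(i + 1, k)]
        cols += [X[:, i] ** 2 for i in range(k)]
    elif order != 1:
        raise ValueError("order must be 1 or 2")
    return np.column_stack(cols)


@dataclass
class PolyModel:
    """Fitted (or specified) polynomial in coded units.

    ``coef`` maps term labels (``Intercept``, ``ratio``, ``ratio:ethanol``,
    ``ethanol^2``, ...) to coefficients. Order-1 models carry 1+k terms,
    order-2 models 1 + k + k(k-1)/2 + k.
    """

    order: int
    factor_names: list[str]
    coef: dict[str, float]
    coded_space: bool = True

    def __post_init__(self) -> None:
        expected = term_labels(self.factor_names, self.order)
        if list(self.coef) != expected:
            # accept any ordering/subset mistakes loudly
            missing = [t for t in expected if t not in self.coef]
            extra = [t for t in self.coef if t not in expected]
            if missing or extra:
                raise ValueError(f"coefficient terms mismatch; missing={missing}, extra={extra}")
            self.coef = {t: self.coef[t] for t in expected}
        if not all(np.isfinite(v) for v in self.coef.values()):
            raise ValueError("coefficients must be finite")

    @property
    def k(self) -> int:
        return len(self.factor_names)

    @property
    def terms(self) -> list[str]:
        return list(self.coef)

    def coef_vector(self) -> np.ndarray:
        return np.array(list(self.coef.values()))

    def predict(self, points) -> np.ndarray | float:
        """Evaluate the polynomial at coded points (length-k or n x k)."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        X = build_model_matrix(np.atleast_2d(pts), self.order)
        out = X @ self.coef_vector()
        return float(out[0]) if single else out

    @classmethod
    def from_coefficients(cls, factor_names, order, values) -> "PolyModel":
        """Build from a coefficient sequence in canonical term order."""
        labels = term_labels(factor_names, order)
        values = list(values)
        if len(values) != len(labels):
            raise ValueError(f"expected {len(labels)} coefficients, got {len(values)}")
        return cls(order=order, factor_names=list(factor_names), coef=dict(zip(labels, values)))


@dataclass
class AnovaTable:
    """ANOVA decomposition plus the fit statistics block.

    ``table`` has one row per source (Model, each term, Residual,
    Lack of Fit, Pure Error, Cor Total) with columns Source, SS, df, MS, F,
    p. ``stats`` holds Std. Dev., Mean, CV%, R2, adjusted/predicted R2 and
    adequate precision. ``term_se`` keeps each coefficient's standard error
    for standardized-effect (Pareto) computation.
    """

    table: pd.DataFrame
    stats: dict[str, float]
    term_se: dict[str, float]
    df_residual: int
    ms_residual: float
    design_kind: str = "custom"
    n_contrast_columns: int | None = None

    def row(self, source: str) -> pd.Series:
        match = self.table[self.table["Source"] == source]
        if match.empty:
            raise KeyError(f"no ANOVA row for source {source!r}")
        return match.iloc[0]

    def formatted(self) -> pd.DataFrame:
        """Display copy with p-values below 1e-4 rendered as '< 0.0001'."""
        out = self.table.copy()
        out["p"] = [
            "" if not np.isfinite(p) else ("< 0.0001" if p < 1e-4 else f"{p:.4f}")
            for p in out["p"]
        ]
        return out


@dataclass
class ParetoEffects:
    """Standardized effects |t| with t and Bonferroni significance limits."""

    effects: pd.DataFrame  # term, t_abs, sign (sorted descending by t_abs)
    t_limit: float
    bonferroni_limit: float
    alpha: float
    df_residual: int
    n_effects: int


class SingularModelError(np.linalg.LinAlgError):
    """Raised when the polynomial basis is rank deficient on the design."""


def _check_lengths(design: DesignMatrix, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != design.n_runs:
        raise ValueError(f"response length {y.shape[0]} != {design.n_runs} design runs")
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    return y


def fit_model(design: DesignMatrix, y, order: int) -> PolyModel:
    """Ordinary-least-squares fit of the order-1 or order-2 polynomial.

    Raises :class:`SingularModelError` naming the aliased terms when the
    basis is rank deficient on this design.
    """
    y = _check_lengths(design, y)
    labels = term_labels(design.factor_names, order)
    X = build_model_matrix(design.levels, order)
    n, p = X.shape
    if n < p:
        raise ValueError(f"{n} runs cannot identify {p} model terms")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        aliased = _aliased_terms(X, labels)
        raise SingularModelError(f"rank-deficient model matrix; aliased terms: {aliased}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return PolyModel(order=order, factor_names=list(design.factor_names), coef=dict(zip(labels, beta)))


def _aliased_terms(X: np.ndarray, labels: list[str]) -> list[str]:
    """Terms whose column adds no rank given the preceding columns."""
    aliased, kept = [], np.empty((X.shape[0], 0))
    for j, lab in enumerate(labels):
        cand = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(cand) == kept.shape[1]:
            aliased.append(lab)
        else:
            kept = cand
    return aliased


def _replicate_groups(levels: np.ndarray) -> list[np.ndarray]:
    """Indices of runs sharing identical coded rows (replicate sets)."""
    rounded = np.round(levels, 12)
    _, inverse = np.unique(rounded, axis=0, return_inverse=True)
    return [np.flatnonzero(inverse == g) for g in range(inverse.max() + 1)]


def anova(model: PolyModel, design: DesignMatrix, y) -> AnovaTable:
    """Full ANOVA table for a fitted polynomial model.

    Term sums of squares are partial (Type III), ``b_j^2 / [(X'X)^-1]_jj``;
    on orthogonal screening/Box-Behnken columns these equal the sequential
    SS. The residual is split into lack of fit and pure error using exact
    replicate rows (the center points); with no replicates the split is
    omitted with a logged notice.
    """
    y = _check_lengths(design, y)
    X = build_model_matrix(design.levels, model.order)
    labels = model.terms
    n, p = X.shape
    beta = model.coef_vector()
    yhat = X @ beta
    resid = y - yhat

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(resid @ resid)
    ss_model = ss_tot - ss_res
    df_model, df_res, df_tot = p - 1, n - p, n - 1
    ms_res = ss_res / df_res if df_res > 0 else np.nan

    xtx_inv = np.linalg.inv(X.T @ X)
    cjj = np.diag(xtx_inv)
    term_ss = {lab: float(beta[j] ** 2 / cjj[j]) for j, lab in enumerate(labels) if lab != "Intercept"}
    term_se = {
        lab: float(np.sqrt(ms_res * cjj[j])) if df_res > 0 else np.nan
        for j, lab in enumerate(labels)
    }

    def f_p(ss: float, df: int) -> tuple[float, float]:
        if df_res <= 0 or df <= 0 or not np.isfinite(ms_res) or ms_res <= 0:
            return np.nan, np.nan
        F = (ss / df) / ms_res
        return F, float(stats.f.sf(F, df, df_res))

    rows = []
    F_m, p_m = f_p(ss_model, df_model)
    rows.append(("Model", ss_model, df_model, ss_model / df_model, F_m, p_m))
    for lab in labels:
        if lab == "Intercept":
            continue
        F_t, p_t = f_p(term_ss[lab], 1)
        rows.append((lab, term_ss[lab], 1, term_ss[lab], F_t, p_t))
    rows.append(("Residual", ss_res, df_res, ms_res, np.nan, np.nan))

    groups = [g for g in _replicate_groups(design.levels) if len(g) > 1]
    if groups:
        ss_pe = float(sum(np.sum((y[g] - y[g].mean()) ** 2) for g in groups))
        df_pe = int(sum(len(g) - 1 for g in groups))
        ss_lof = ss_res - ss_pe
        df_lof = df_res - df_pe
        if df_lof > 0 and df_pe > 0:
            ms_lof, ms_pe = ss_lof / df_lof, ss_pe / df_pe
            F_lof = ms_lof / ms_pe if ms_pe > 0 else np.nan
            p_lof = float(stats.f.sf(F_lof, df_lof, df_pe)) if np.isfinite(F_lof) else np.nan
            rows.append(("Lack of Fit", ss_lof, df_lof, ms_lof, F_lof, p_lof))
            rows.append(("Pure Error", ss_pe, df_pe, ms_pe, np.nan, np.nan))
        else:
            log.info("replicates present but no lack-of-fit degrees of freedom; split omitted")
    else:
        log.info("no replicated runs; lack-of-fit split omitted")
    rows.append(("Cor Total", ss_tot, df_tot, np.nan, np.nan, np.nan))

    table = pd.DataFrame(rows, columns=["Source", "SS", "df", "MS", "F", "p"])
    H_diag = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
    out = AnovaTable(
        table=table,
        stats={},
        term_se=term_se,
        df_residual=df_res,
        ms_residual=ms_res,
        design_kind=design.design_kind,
        n_contrast_columns=(
            design.levels.shape[1] + design.dummy_levels.shape[1]
            if getattr(design, "dummy_levels", None) is not None
            else None
        ),
    )
    out.stats = fit_statistics(
        out,
        y=y,
        yhat=yhat,
        leverages=H_diag,
        n_terms=p,
    )
    return out


def fit_statistics(
    anova_table: AnovaTable,
    *,
    y: np.ndarray,
    yhat: np.ndarray,
    leverages: np.ndarray,
    n_terms: int,
) -> dict[str, float]:
    """Design-of-experiments fit statistics block.

    R2 = 1 - SS_res/SS_tot; adjusted R2 penalizes by residual df;
    predicted R2 = 1 - PRESS/SS_tot with PRESS the leave-one-out error sum
    of squares from leverages; CV% = 100 sqrt(MS_res)/mean(Y); adequate
    precision = (max yhat - min yhat) / sqrt(p MS_res / n).
    """
    t = anova_table.table
    ss_res = float(t.loc[t.Source == "Residual", "SS"].iloc[0])
    df_res = int(t.loc[t.Source == "Residual", "df"].iloc[0])
    ss_tot = float(t.loc[t.Source == "Cor Total", "SS"].iloc[0])
    df_tot = int(t.loc[t.Source == "Cor Total", "df"].iloc[0])
    n = len(y)
    resid = y - yhat
    ms_res = anova_table.ms_residual

    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    adj_r2 = 1.0 - (ss_res / df_res) / (ss_tot / df_tot) if df_res > 0 and ss_tot > 0 else np.nan

    ok = leverages < 1.0 - 1e-10
    if not np.all(ok):
        log.warning("%d leverage-one run(s) excluded from PRESS", int((~ok).sum()))
    press = float(np.sum((resid[ok] / (1.0 - leverages[ok])) ** 2))
    pred_r2 = 1.0 - press / ss_tot if ss_tot > 0 else np.nan

    mean_y = float(np.mean(y))
    std_dev = float(np.sqrt(ms_res)) if df_res > 0 else np.nan
    cv = 100.0 * std_dev / mean_y if mean_y != 0 else np.nan
    adeq = (
        float((yhat.max() - yhat.min()) / np.sqrt(n_terms * ms_res / n))
        if df_res > 0 and ms_res > 0
        else np.nan
    )
    return {
        "std_dev": std_dev,
        "mean": mean_y,
        "cv_percent": cv,
        "r_squared": r2,
        "adj_r_squared": adj_r2,
        "pred_r_squared": pred_r2,
        "press": press,
        "adeq_precision": adeq,
    }


def pareto_effects(
    model: PolyModel,
    anova_table: AnovaTable,
    alpha: float = 0.05,
    n_effects: int | None = None,
) -> ParetoEffects:
    """Standardized effects |t| = |b|/se(b) with significance limits.

    ``t_limit`` is the two-sided t quantile at ``alpha`` on the residual df;
    the Bonferroni limit divides ``alpha`` by the number of candidate
    effects ``m``. For a Plackett-Burman design ``m`` defaults to all 11
    generator contrast columns; otherwise to the number of model effects.
    """
    df_res = anova_table.df_residual
    if df_res < 1:
        raise ValueError("Pareto effects need at least 1 residual degree of freedom")
    rows = []
    for lab, coefficient in model.coef.items():
        if lab == "Intercept":
            continue
        se = anova_table.term_se[lab]
        rows.append((lab, abs(coefficient) / se, float(np.sign(coefficient))))
    eff = pd.DataFrame(rows, columns=["term", "t_abs", "sign"])
    eff = eff.sort_values("t_abs", ascending=False, ignore_index=True)
    if n_effects is None:
        if anova_table.design_kind == "pbd" and anova_table.n_contrast_columns:
            n_effects = anova_table.n_contrast_columns
        else:
            n_effects = len(eff)
    t_limit = float(stats.t.ppf(1.0 - alpha / 2.0, df_res))
    bonf = float(stats.t.ppf(1.0 - alpha / (2.0 * n_effects), df_res))
    return ParetoEffects(
        effects=eff,
        t_limit=t_limit,
        bonferroni_limit=bonf,
        alpha=alpha,
        df_residual=df_res,
        n_effects=n_effects,
    )
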