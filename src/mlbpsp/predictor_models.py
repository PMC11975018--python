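"""Multinomial logistic regression of phenotype membership on baseline predictors.

Each predictor is first fitted alone (univariable stage); predictors whose
overall likelihood-ratio p is at most 0.10 enter a joint model together with
forced covariates (education), which is pruned by iterative backward
elimination until every retained predictor has at least one contrast with
p <= 0.05.  Inference per contrast (each phenotype vs the reference) is
Wald: OR = exp(coef), 95% CI = exp(coef +/- 1.96 se), with BH adjustment
across the three contrasts of a predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from mlbpsp.phenotype_characterization import bh_adjust


@dataclass
class ContrastEstimate:
    contrast: str
    coefficient: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    p_adj: float = float("nan")
    separated: bool = False


@dataclass
class PredictorResult:
    """Per-predictor multinomial regression estimates for all contrasts."""

    predictor: str
    stage: str  # "univariable" | "multivariable"
    contrasts: list[ContrastEstimate]
    overall_p: float
    transform: str = "none"
    separated: bool = False

    def contrast(self, name: str) -> ContrastEstimate:
        for c in self.contrasts:
            if c.contrast == name:
                return c
        raise KeyError(name)

    @property
    def min_contrast_p(self) -> float:
        return min(c.p for c in self.contrasts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "predictor": self.predictor,
                    "stage": self.stage,
                    "contrast": c.contrast,
                    "OR": c.odds_ratio,
                    "ci_low": c.ci_low,
                    "ci_high": c.ci_high,
                    "p": c.p,
                    "p_adj": c.p_adj,
                }
                for c in self.contrasts
            ]
        )


@dataclass
class ModelSelectionTrace:
    """History of the screen-then-backward-eliminate selection."""

    screened_in: list[str]
    forced: list[str]
    eliminated: list[tuple[str, float]] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)


def wald_ci(coefficient: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Wald confidence interval for an odds ratio: exp(coef -/+ z*se)."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    if not 0.0 <= level < 1.0:
        raise ValueError("level must be in [0, 1)")
    z = stats.norm.ppf((1.0 + level) / 2.0)
    return float(np.exp(coefficient - z * se)), float(np.exp(coefficient + z * se))


def apply_predictor_transform(values: pd.Series, transform: str) -> pd.Series:
    """none | log10 | sqrt, applied element-wise."""
    if transform == "none":
        return values.astype(float)
    if transform == "log10":
        if (values <= 0).any():
            raise ValueError("log10 transform requires strictly positive values")
        return np.log10(values.astype(float))
    if transform == "sqrt":
        if (values < 0).any():
            raise ValueError("sqrt transform requires non-negative values")
        return np.sqrt(values.astype(float))
    raise ValueError(f"unknown transform {transform!r}")


def _encode_labels(labels: pd.Series) -> tuple[np.ndarray, list]:
    """Map labels to 0..k-1 with the smallest label (reference) at 0."""
    cats = sorted(pd.unique(labels.dropna()))
    mapping = {c: i for i, c in enumerate(cats)}
    return labels.map(mapping).to_numpy(dtype=int), cats


def _fit_mnlogit(endog: np.ndarray, exog: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MNLogit(endog, exog)
        try:
            return model.fit(method="newton", maxiter=200, disp=0)
        except np.linalg.LinAlgError:
            # singular Hessian under (quasi-)separation; BFGS walks toward
            # the boundary and the huge coefficients get flagged downstream
            return model.fit(method="bfgs", maxiter=500, disp=0)


def _contrasts_from_fit(res, cats, col: int, level: float = 0.95) -> list[ContrastEstimate]:
    """Wald contrasts for one predictor column, BH-adjusted across contrasts."""
    ref = cats[0]
    out = []
    params = np.asarray(res.params)  # (n_exog, k-1)
    bse = np.asarray(res.bse)
    for j, cat in enumerate(cats[1:]):
        coef = float(params[col, j])
        se = float(bse[col, j])
        separated = not np.isfinite(se) or se > 1e3 or abs(coef) > 30
        if separated:
            out.append(
                ContrastEstimate(
                    contrast=f"{cat} vs {ref}",
                    coefficient=coef,
                    se=se,
                    odds_ratio=float(np.exp(np.clip(coef, -700, 700))),
                    ci_low=0.0,
                    ci_high=float("inf"),
                    p=float("nan"),
                    separated=True,
                )
            )
            continue
        lo, hi = wald_ci(coef, se, level)
        z = coef / se
        p = 2.0 * stats.norm.sf(abs(z))
        out.append(
            ContrastEstimate(
                contrast=f"{cat} vs {ref}",
                coefficient=coef,
                se=se,
                odds_ratio=float(np.exp(coef)),
                ci_low=lo,
                ci_high=hi,
                p=float(p),
            )
        )
    ps = np.array([c.p for c in out])
    if np.isfinite(ps).all():
        adj = bh_adjust(ps, m=len(ps))
        for c, a in zip(out, adj):
            c.p_adj = float(a)
    return out


def univariable_multinomial(
    values: pd.Series, labels: pd.Series, transform: str = "none"
) -> PredictorResult:
    """Single-predictor multinomial logit with the smallest label as reference.

    The overall p is the likelihood-ratio test of the predictor block
    against the intercept-only model.  For a binary predictor the fitted
    contrast odds ratios equal the 2x2 contingency-table sample odds ratios
    (the model is saturated).
    """
    df = pd.DataFrame({"x": values, "y": labels}).dropna()
    x = apply_predictor_transform(df["x"], transform)
    if x.nunique() < 2:
        raise ValueError(f"predictor {values.name!r} is constant")
    endog, cats = _encode_labels(df["y"])
    if len(cats) < 2:
        raise ValueError("labels contain a single class")
    exog = np.column_stack([np.ones(len(x)), x.to_numpy()])

    res = _fit_mnlogit(endog, exog)
    null = _fit_mnlogit(endog, exog[:, :1])
    lr = 2.0 * (res.llf - null.llf)
    df_diff = len(cats) - 1
    overall_p = float(stats.chi2.sf(max(lr, 0.0), df_diff))

    contrasts = _contrasts_from_fit(res, cats, col=1)
    separated = any(c.separated for c in contrasts)
    return PredictorResult(
        predictor=str(values.name),
        stage="univariable",
        contrasts=contrasts,
        overall_p=overall_p,
        transform=transform,
        separated=separated,
    )


def screen_predictors(results: list[PredictorResult], threshold: float = 0.10) -> list[str]:
    """Predictors whose overall likelihood-ratio p is at most the threshold."""
    return [r.predictor for r in results if r.overall_p <= threshold]


def _check_collinearity(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(mat)), mat]))
    if rank < X.shape[1] + 1:
        corr = np.corrcoef(mat, rowvar=False)
        cols = list(X.columns)
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                if abs(corr[i, j]) > 1.0 - 1e-10:
                    raise ValueError(
                        f"perfectly collinear predictors: {cols[i]!r} and {cols[j]!r}"
                    )
        raise ValueError("predictor matrix is rank deficient")


def multivariable_multinomial(
    predictors: pd.DataFrame,
    labels: pd.Series,
    forced: list[str] | None = None,
    retain_threshold: float = 0.05,
    transforms: dict[str, str] | None = None,
) -> tuple[list[PredictorResult], ModelSelectionTrace]:
    """Joint multinomial fit with iterative backward elimination.

    At each round the non-forced predictor whose best (minimum) contrast p is
    largest is removed if that p exceeds ``retain_threshold``; the model is
    refitted until all retained predictors have some contrast p below the
    threshold.  Forced covariates are never removed.
    """
    forced = list(forced or [])
    transforms = transforms or {}
    candidates = [c for c in predictors.columns if c not in forced]
    trace = ModelSelectionTrace(screened_in=list(candidates), forced=forced)

    df = predictors.copy()
    for col in df.columns:
        df[col] = apply_predictor_transform(df[col], transforms.get(col, "none"))
    df = df.join(labels.rename("__y__"), how="inner").dropna()
    if df.empty:
        raise ValueError("no complete cases")

    current = forced + candidates

    def _fit(cols: list[str]):
        X = df[cols]
        _check_collinearity(X)
        endog, cats = _encode_labels(df["__y__"])
        exog = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
        res = _fit_mnlogit(endog, exog)
        results = []
        for i, col in enumerate(cols, start=1):
            contrasts = _contrasts_from_fit(res, cats, col=i)
            results.append(
                PredictorResult(
                    predictor=col,
                    stage="multivariable",
                    contrasts=contrasts,
                    overall_p=float("nan"),
                    transform=transforms.get(col, "none"),
                    separated=any(c.separated for c in contrasts),
                )
            )
        return results

    try:
        results = _fit(current)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - solver-dependent
        raise RuntimeError(f"multivariable fit failed: {exc}") from exc

    while True:
        removable = [r for r in results if r.predictor not in forced]
        if not removable:
            break
        worst = max(removable, key=lambda r: r.min_contrast_p)
        if worst.min_contrast_p <= retain_threshold:
            break
        trace.eliminated.append((worst.predictor, float(worst.min_contrast_p)))
        current = [c for c in current if c != worst.predictor]
        results = _fit(current)

    trace.retained = [r.predictor for r in results if r.predictor not in forced]
    return results, trace
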