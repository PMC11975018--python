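"""Per-feature mixed-effects trajectory models and random-effect extraction.

Step one of the two-step phenotyping: each longitudinal feature is fitted
with a linear mixed model with fixed and random quadratic time trends,

    y_ij = b0 + b1*t_ij + b2*t_ij^2 + u0i + u1i*t_ij + u2i*t_ij^2 + e_ij,

by maximum likelihood using all observed rows (likelihood-based handling of
missing-at-random data, no imputation).  Empirical-Bayes (BLUP) predictions
of the three subject-level effects become the participant features used for
clustering: 3 per longitudinal feature, 51 for the default 17-feature roster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLMParams
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from mlbpsp.synthetic_cohort import CohortPanel

RANDOM_EFFECT_SUFFIXES = ("intercept", "slope", "quad")

#: Months per visit unit; time is coded t = visit_month / 6 in {0, 1, 2, 3}.
MONTHS_PER_UNIT = 6.0


@dataclass(frozen=True)
class FeatureSpec:
    """Name, transform, and non-negativity contract of one feature."""

    name: str
    transform: str = "sqrt"  # "sqrt" | "none"
    nonnegative: bool = True

    def __post_init__(self) -> None:
        if self.transform not in ("sqrt", "none"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.transform == "sqrt" and not self.nonnegative:
            raise ValueError("square-root transform requires the non-negativity flag")


@dataclass
class MixedModelFit:
    """Fitted trajectory model for one feature.

    ``beta`` are the fixed effects (intercept, linear, quadratic) on the
    transformed scale per visit unit; ``cov_re`` is the 3x3 random-effect
    covariance G; ``sigma2`` the residual variance; ``ranef`` a DataFrame of
    empirical-Bayes effects indexed by pid with columns matching
    ``RANDOM_EFFECT_SUFFIXES``.
    """

    feature: str
    beta: np.ndarray
    cov_re: np.ndarray
    sigma2: float
    ranef: pd.DataFrame
    converged: bool = True
    fallback_diagonal: bool = False
    n_obs: int = 0
    loglike: float = float("nan")


@dataclass
class RandomEffectsMatrix:
    """Participant x (3 * n_features) empirical-Bayes feature matrix."""

    values: pd.DataFrame  # index = pid, columns = <feature>__<suffix>
    fallback_cells: list[tuple[object, str]] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def transform_feature(values, spec: FeatureSpec):
    """Apply the spec's transform element-wise; missing values pass through."""
    arr = pd.Series(values, dtype=float) if not isinstance(values, pd.Series) else values.astype(float)
    if spec.transform == "none":
        return arr.copy()
    neg = arr < 0
    if neg.any():
        where = arr.index[neg].tolist()
        raise ValueError(
            f"feature {spec.name!r}: negative values under square-root transform "
            f"at rows {where}"
        )
    return np.sqrt(arr)


def _transform_panel_column(panel: CohortPanel, spec: FeatureSpec) -> pd.DataFrame:
    if spec.name not in panel.feature_names:
        raise KeyError(f"feature {spec.name!r} not in panel")
    sub = panel.data[["pid", "visit_month", spec.name]].copy()
    if spec.transform == "sqrt":
        neg = sub[spec.name] < 0
        if neg.any():
            bad = sub.loc[neg, ["pid", "visit_month"]].itertuples(index=False)
            locs = ", ".join(f"(pid={p}, visit={v})" for p, v in bad)
            raise ValueError(
                f"feature {spec.name!r}: negative raw values under square-root "
                f"transform at {locs}"
            )
        sub[spec.name] = np.sqrt(sub[spec.name])
    return sub.dropna(subset=[spec.name])


def _degenerate_fit(feature: str, value: float, pids) -> MixedModelFit:
    ranef = pd.DataFrame(
        0.0, index=pd.Index(pids, name="pid"), columns=list(RANDOM_EFFECT_SUFFIXES)
    )
    return MixedModelFit(
        feature=feature,
        beta=np.array([value, 0.0, 0.0]),
        cov_re=np.zeros((3, 3)),
        sigma2=0.0,
        ranef=ranef,
        converged=True,
        fallback_diagonal=False,
        n_obs=len(pids),
    )


def _empirical_bayes(
    sub: pd.DataFrame, ycol: str, beta: np.ndarray, G: np.ndarray, sigma2: float
) -> pd.DataFrame:
    """BLUPs b_i = G Z_i' V_i^{-1} (y_i - X_i beta), V_i = Z_i G Z_i' + s2 I."""
    out = {}
    for pid, grp in sub.groupby("pid", sort=True):
        t = grp["visit_month"].to_numpy(dtype=float) / MONTHS_PER_UNIT
        Z = np.column_stack([np.ones_like(t), t, t * t])
        resid = grp[ycol].to_numpy(dtype=float) - Z @ beta
        V = Z @ G @ Z.T + sigma2 * np.eye(len(t))
        # pinv guards the degenerate G = 0, sigma2 = 0 corner
        out[pid] = G @ Z.T @ np.linalg.pinv(V) @ resid
    return pd.DataFrame.from_dict(out, orient="index", columns=list(RANDOM_EFFECT_SUFFIXES)).rename_axis("pid")


def fit_feature_lmm(panel: CohortPanel, spec: FeatureSpec) -> MixedModelFit:
    """ML fit of the quadratic-time random-slope model for one feature.

    Time is coded in visit units t = visit_month / 6.  The random-effect
    covariance is unstructured; on non-convergence the model is refitted with
    a diagonal G and the fallback flag is set.  Raises if fewer than three
    distinct visit times are observed (quadratic term inestimable) or if both
    fits fail.
    """
    sub = _transform_panel_column(panel, spec)
    times = np.sort(sub["visit_month"].unique())
    if len(times) < 3:
        raise ValueError(
            f"feature {spec.name!r}: {len(times)} distinct visit times; "
            "need >= 3 to estimate a quadratic trend"
        )
    y = sub[spec.name].to_numpy(dtype=float)
    if np.ptp(y) == 0.0:
        return _degenerate_fit(spec.name, y[0], sub["pid"].unique())

    t = sub["visit_month"].to_numpy(dtype=float) / MONTHS_PER_UNIT
    X = np.column_stack([np.ones_like(t), t, t * t])
    groups = sub["pid"].to_numpy()

    model = sm.MixedLM(y, X, groups=groups, exog_re=X)

    def _fit(free=None, method="lbfgs"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            return model.fit(reml=False, free=free, maxiter=500, method=method)

    # gradient-based fit is fast but often stalls when the quadratic-slope
    # variance sits near the boundary; Powell is the reliable fallback
    fallback = False
    res, converged = None, False
    diag_free = MixedLMParams.from_components(fe_params=np.ones(3), cov_re=np.eye(3))
    for free, method in ((None, "lbfgs"), (None, "powell"), (diag_free, "powell")):
        try:
            res = _fit(free=free, method=method)
            converged = bool(res.converged)
        except (np.linalg.LinAlgError, ValueError):
            converged = False
        if converged:
            fallback = free is not None
            break
    if not converged:
        raise RuntimeError(
            f"feature {spec.name!r}: mixed-model fit failed to converge "
            "under both unstructured and diagonal random-effect covariance"
        )

    beta = np.asarray(res.fe_params, dtype=float)
    G = np.asarray(res.cov_re, dtype=float)
    sigma2 = float(res.scale)
    ranef = _empirical_bayes(sub, spec.name, beta, G, sigma2)
    return MixedModelFit(
        feature=spec.name,
        beta=beta,
        cov_re=G,
        sigma2=sigma2,
        ranef=ranef,
        converged=converged,
        fallback_diagonal=fallback,
        n_obs=len(sub),
        loglike=float(res.llf),
    )


def extract_random_effects(
    fits: list[MixedModelFit], participants=None
) -> RandomEffectsMatrix:
    """Assemble the N x (3F) participant feature matrix in declared fit order.

    Participants with no observations for a feature receive that feature's
    prior mean (0, 0, 0); those cells are recorded in ``fallback_cells``.
    """
    if not fits:
        raise ValueError("no fits supplied")
    if participants is None:
        universe = pd.Index(sorted(set().union(*(set(f.ranef.index) for f in fits))), name="pid")
    else:
        universe = pd.Index(participants, name="pid")
        covered = set().union(*(set(f.ranef.index) for f in fits))
        orphans = [p for p in universe if p not in covered]
        if orphans:
            raise ValueError(f"participants present in no fit: {orphans}")

    blocks = []
    fallback_cells: list[tuple[object, str]] = []
    for fit in fits:
        cols = [f"{fit.feature}__{s}" for s in RANDOM_EFFECT_SUFFIXES]
        block = fit.ranef.reindex(universe)
        missing = block.index[block.isna().any(axis=1)]
        fallback_cells.extend((pid, fit.feature) for pid in missing)
        block = block.fillna(0.0)
        block.columns = cols
        blocks.append(block)
    values = pd.concat(blocks, axis=1)
    return RandomEffectsMatrix(values=values, fallback_cells=fallback_cells)


def default_feature_specs(names) -> list[FeatureSpec]:
    """Square-root specs for a roster of non-negative skewed features."""
    return [FeatureSpec(name=n) for n in names]
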