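"""Baseline group comparisons and longitudinal outcome models.

Numeric baseline variables are compared across phenotypes with one-way
ANOVA, categorical ones with Pearson chi-square (no continuity correction);
pairwise contrasts of the same kind are adjusted with the Benjamini-Hochberg
step-up procedure (family size 3 for the comparisons against the reference
phenotype, 6 for all pairs).  Longitudinal outcomes are modelled with a
random-intercept linear mixed model with phenotype, time, and their
interaction as fixed effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from mlbpsp.synthetic_cohort import CohortPanel
from mlbpsp.trajectory_features import MONTHS_PER_UNIT, FeatureSpec, transform_feature


@dataclass
class ComparisonRow:
    """One baseline variable compared across phenotypes."""

    variable: str
    kind: str  # "numeric" | "categorical"
    group_summary: dict
    statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns: contrast, statistic, p, p_adj
    family: str  # "vs_ref" (k=3) | "all_pairs" (k=6)


@dataclass
class LongitudinalContrast:
    """Fixed-effect contrasts of one outcome's trajectory model."""

    outcome: str
    fixed_effects: pd.DataFrame  # term, estimate, se, p
    main_contrasts: pd.DataFrame  # contrast, estimate, se, p, p_adj
    interaction_contrasts: pd.DataFrame
    converged: bool = True


def bh_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sort ascending, multiply p_(i) by m/i, enforce monotonicity from the
    largest down, cap at 1.  ``m`` defaults to the number of p-values and
    must be at least that.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if m is None:
        m = n
    if m < n:
        raise ValueError("family size m must be >= number of p-values")
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def _pairs(groups: list, family: str) -> list[tuple]:
    if family == "vs_ref":
        ref = groups[0]
        return [(ref, g) for g in groups[1:]]
    if family == "all_pairs":
        return list(combinations(groups, 2))
    raise ValueError(f"unknown family {family!r}")


def compare_baseline_variable(
    values: pd.Series,
    labels: pd.Series,
    kind: str,
    family: str = "vs_ref",
    spec: FeatureSpec | None = None,
) -> ComparisonRow:
    """ANOVA (numeric) or Pearson chi-square (categorical) across phenotypes.

    ``values`` and ``labels`` are aligned by index; missing values are
    dropped.  Numeric variables may be pre-transformed via ``spec``.
    Pairwise contrasts use the same kind of test and are BH-adjusted.
    """
    df = pd.DataFrame({"value": values, "label": labels}).dropna()
    groups = sorted(df["label"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups")
    for g in groups:
        if (df["label"] == g).sum() == 0:
            raise ValueError(f"group {g} has zero observations")

    if kind == "numeric":
        work = df.copy()
        if spec is not None:
            work["value"] = transform_feature(work["value"], spec)
        samples = [work.loc[work["label"] == g, "value"].to_numpy() for g in groups]
        stat, p = stats.f_oneway(*samples)
        summary = {
            g: (float(np.mean(s)), float(np.std(s, ddof=1)) if len(s) > 1 else 0.0)
            for g, s in zip(groups, samples)
        }
        rows = []
        for a, b in _pairs(groups, family):
            sa = work.loc[work["label"] == a, "value"]
            sb = work.loc[work["label"] == b, "value"]
            t, pp = stats.ttest_ind(sa, sb, equal_var=True)
            rows.append({"contrast": f"{b} vs {a}", "statistic": float(t), "p": float(pp)})
    elif kind == "categorical":
        table = pd.crosstab(df["value"], df["label"])
        expected = stats.contingency.expected_freq(table.to_numpy())
        if (expected < 1).any():
            import warnings

            warnings.warn(
                f"{values.name}: expected cell count below 1 in the overall table",
                stacklevel=2,
            )
        stat, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
        totals = df.groupby("label").size()
        summary = {
            g: {
                lvl: (int(cnt), float(cnt / totals[g]))
                for lvl, cnt in table[g].items()
            }
            for g in groups
        }
        rows = []
        for a, b in _pairs(groups, family):
            sub = table[[a, b]].loc[table[[a, b]].sum(axis=1) > 0]
            chi, pp, _, _ = stats.chi2_contingency(sub.to_numpy(), correction=False)
            rows.append({"contrast": f"{b} vs {a}", "statistic": float(chi), "p": float(pp)})
    else:
        raise ValueError(f"unknown variable kind {kind!r}")

    pairwise = pd.DataFrame(rows)
    k_family = len(rows)
    pairwise["p_adj"] = bh_adjust(pairwise["p"].to_numpy(), m=k_family)
    return ComparisonRow(
        variable=str(values.name),
        kind=kind,
        group_summary=summary,
        statistic=float(stat),
        p_value=float(p),
        pairwise=pairwise,
        family=family,
    )


def fit_outcome_trajectory_lmm(
    panel: CohortPanel,
    labels: pd.Series,
    outcome: str,
    spec: FeatureSpec | None = None,
) -> LongitudinalContrast:
    """Random-intercept LMM: outcome ~ phenotype * time, ML estimation.

    The reference phenotype is the smallest label (label 1 after severity
    ordering).  Main-effect and interaction contrasts against the reference
    are each BH-adjusted within their own family.
    """
    if outcome not in panel.feature_names:
        raise KeyError(f"outcome {outcome!r} not in panel")
    df = panel.data[["pid", "visit_month", outcome]].dropna().copy()
    df["t"] = df["visit_month"] / MONTHS_PER_UNIT
    df["phen"] = df["pid"].map(labels)
    df = df.dropna(subset=["phen"])
    df = df.rename(columns={outcome: "y"})
    if spec is not None:
        df["y"] = transform_feature(df["y"], FeatureSpec(name=outcome, transform=spec.transform))

    counts = df.groupby("phen")["pid"].nunique()
    if len(counts) < 2:
        raise ValueError("all participants fall in a single phenotype")
    small = counts.index[counts < 2].tolist()
    if small:
        raise ValueError(f"phenotypes with < 2 participants: {small}")
    times = df["visit_month"].nunique()
    if times < 2:
        raise ValueError(f"outcome {outcome!r} observed at {times} visit(s); need >= 2")

    model = smf.mixedlm("y ~ C(phen) * t", df, groups=df["pid"])
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        res = model.fit(reml=False, maxiter=200)

    fe = pd.DataFrame(
        {
            "term": res.fe_params.index,
            "estimate": res.fe_params.to_numpy(),
            "se": res.bse_fe.to_numpy(),
            "p": res.pvalues[res.fe_params.index].to_numpy(),
        }
    )

    ref = sorted(counts.index)[0]
    others = [g for g in sorted(counts.index) if g != ref]

    def _contrast_frame(term_fmt: str) -> pd.DataFrame:
        rows = []
        for g in others:
            term = term_fmt.format(g=g)
            if term not in res.fe_params.index:
                continue
            rows.append(
                {
                    "contrast": f"{g} vs {ref}",
                    "estimate": float(res.fe_params[term]),
                    "se": float(res.bse_fe[term]),
                    "p": float(res.pvalues[term]),
                }
            )
        out = pd.DataFrame(rows)
        if len(out):
            out["p_adj"] = bh_adjust(out["p"].to_numpy(), m=len(out))
        return out

    main = _contrast_frame("C(phen)[T.{g}]")
    interaction = _contrast_frame("C(phen)[T.{g}]:t")
    return LongitudinalContrast(
        outcome=outcome,
        fixed_effects=fe,
        main_contrasts=main,
        interaction_contrasts=interaction,
        converged=bool(res.converged),
    )
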