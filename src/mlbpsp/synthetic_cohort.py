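"""Synthetic longitudinal cohort generator.

Produces ground-truth-labelled cohorts with the statistical structure the
phenotyping pipeline assumes: a mixture of latent phenotype archetypes, each
defining quadratic mean trajectories per feature on a transformed
(square-root) scale, subject-level random intercepts/slopes, Gaussian
residual noise, and configurable visit- and item-level missingness.  Raw
stored values are the squares of the latent values (clamped at zero), so the
pipeline's square-root transform recovers approximately Gaussian structure
by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default 17-feature roster: 7 neurocognitive domain deficit scores,
#: 4 depression-inventory subscales, 5 self-reported functioning components,
#: 1 daily-living dependence total.  All right-skewed, non-negative raw scores.
DEFAULT_FEATURES: tuple[str, ...] = (
    "dds_verbal_fluency",
    "dds_processing_speed",
    "dds_learning",
    "dds_recall",
    "dds_executive",
    "dds_working_memory",
    "dds_motor",
    "bdi_cognitive",
    "bdi_somatic",
    "bdi_affective",
    "bdi_apathy",
    "paofi_memory",
    "paofi_language",
    "paofi_hands",
    "paofi_sensory",
    "paofi_cognition",
    "iadl_total",
)

DEFAULT_VISIT_MONTHS: tuple[int, ...] = (0, 6, 12, 18)

#: Default mixture weights of the four archetypes.
DEFAULT_WEIGHTS: tuple[float, ...] = (0.456, 0.213, 0.192, 0.138)

#: Default per-visit probabilities that the whole visit is absent
#: (baseline is never deleted).
DEFAULT_VISIT_MISS_RATES: tuple[float, ...] = (0.0, 0.0, 0.083, 0.194)

#: Default per-cell item missingness; solves 1-(1-r)^(17*4) = 0.283 so that
#: about 28.3% of participants miss at least one feature cell.
DEFAULT_ITEM_MISS_RATE: float = 1.0 - (1.0 - 0.283) ** (1.0 / 68.0)

#: Default per-phenotype binary comorbidity prevalences (P1, P2, P3, P4).
DEFAULT_COMORBIDITY_PREVALENCE: dict[str, tuple[float, ...]] = {
    "chronic_pulmonary_disease": (0.0563, 0.0833, 0.1134, 0.20),
    "diabetes": (0.0736, 0.1019, 0.0928, 0.1714),
    "hypertension": (0.1905, 0.1481, 0.1546, 0.2571),
    "hyperlipidemia": (0.0952, 0.1389, 0.1134, 0.1143),
}

#: Default per-phenotype Poisson rates for count covariates
#: (concomitant non-ART medication counts, medians about 1/2/2/3).
DEFAULT_COUNT_RATES: dict[str, tuple[float, ...]] = {
    "polypharmacy": (1.5, 2.6, 2.6, 3.3),
}

#: Default per-phenotype (mean, sd) for continuous baseline covariates.
DEFAULT_CONTINUOUS_PARAMS: dict[str, tuple[tuple[float, float], ...]] = {
    "education": ((13.5, 2.4), (12.6, 2.4), (12.3, 2.4), (12.2, 2.4)),
    "creatinine": ((0.97, 0.23), (0.95, 0.25), (0.92, 0.18), (0.94, 0.28)),
    "hematocrit": ((41.7, 4.4), (41.1, 4.2), (40.6, 4.1), (41.2, 5.0)),
}


@dataclass(frozen=True)
class PhenotypeArchetype:
    """One latent phenotype: mean trajectories and variance components.

    Trajectory coefficients are on the transformed (square-root) scale per
    visit unit of time (one unit = 6 months): value = a + b*t + c*t^2.

    Parameters
    ----------
    label : int
        Phenotype index (1-based).
    weight : float
        Mixture proportion in [0, 1].
    trajectories : mapping of feature name -> (a, b, c)
    random_effect_cov : mapping of feature name -> 3x3 PSD covariance of the
        subject-level (intercept, linear, quadratic) random effects.
    residual_sd : mapping of feature name -> residual standard deviation.
    """

    label: int
    weight: float
    trajectories: Mapping[str, tuple[float, float, float]]
    random_effect_cov: Mapping[str, np.ndarray]
    residual_sd: Mapping[str, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"archetype {self.label}: weight {self.weight} not in [0, 1]")
        for name, cov in self.random_effect_cov.items():
            cov = np.asarray(cov, dtype=float)
            if cov.shape != (3, 3):
                raise ValueError(f"archetype {self.label}, feature {name!r}: G must be 3x3")
            if not np.allclose(cov, cov.T):
                raise ValueError(f"archetype {self.label}, feature {name!r}: G not symmetric")
            eigvals = np.linalg.eigvalsh(cov)
            if eigvals.min() < -1e-10:
                raise ValueError(
                    f"archetype {self.label}, feature {name!r}: G not positive semi-definite"
                )
        for name, sd in self.residual_sd.items():
            if sd < 0:
                raise ValueError(f"archetype {self.label}, feature {name!r}: residual sd < 0")

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.trajectories)


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a simulated cohort."""

    n_participants: int = 506
    visit_months: tuple[int, ...] = DEFAULT_VISIT_MONTHS
    miss_visit_rates: tuple[float, ...] = DEFAULT_VISIT_MISS_RATES
    item_miss_rate: float = DEFAULT_ITEM_MISS_RATE
    seed: int = 0
    comorbidity_prevalence: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_PREVALENCE)
    )
    count_rates: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_COUNT_RATES)
    )
    continuous_params: Mapping[str, tuple[tuple[float, float], ...]] = field(
        default_factory=lambda: dict(DEFAULT_CONTINUOUS_PARAMS)
    )

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        months = tuple(self.visit_months)
        if any(b <= a for a, b in zip(months, months[1:])):
            raise ValueError("visit_months must be strictly increasing")
        if len(self.miss_visit_rates) != len(months):
            raise ValueError("miss_visit_rates must have one entry per visit")
        for r in (*self.miss_visit_rates, self.item_miss_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missingness rate {r} not in [0, 1]")

    @property
    def visit_units(self) -> np.ndarray:
        """Time in visit units (months / 6)."""
        return np.asarray(self.visit_months, dtype=float) / 6.0


@dataclass
class CohortPanel:
    """Long-format repeated-measures table with optional truth labels.

    ``data`` has one row per (participant, visit): columns ``pid``,
    ``visit_month``, then one column per feature (NaN = missing).  ``truth``
    is a per-participant phenotype label Series (index = pid) when the panel
    is synthetic.
    """

    data: pd.DataFrame
    truth: pd.Series | None = None
    n_removed: int = 0

    def __post_init__(self) -> None:
        required = {"pid", "visit_month"}
        if not required.issubset(self.data.columns):
            raise ValueError("panel data must have 'pid' and 'visit_month' columns")
        dup = self.data.duplicated(subset=["pid", "visit_month"])
        if dup.any():
            rows = self.data.index[dup].tolist()
            raise ValueError(f"duplicate (pid, visit_month) rows at index {rows}")

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("pid", "visit_month")]

    @property
    def participants(self) -> np.ndarray:
        return self.data["pid"].unique()

    def baseline(self) -> pd.DataFrame:
        """Rows at the earliest visit, indexed by pid."""
        first = self.data["visit_month"].min()
        return self.data[self.data["visit_month"] == first].set_index("pid")


def _check_weights(archetypes: Sequence[PhenotypeArchetype], tol: float = 5e-3) -> None:
    # tolerance accommodates rounded published proportions (e.g. 45.6 + 21.3
    # + 19.2 + 13.8 = 99.9%); draws use the renormalized weights
    total = sum(a.weight for a in archetypes)
    if abs(total - 1.0) > tol:
        raise ValueError(f"archetype weights sum to {total}, expected 1.0")


def simulate_cohort(
    config: CohortConfig, archetypes: Sequence[PhenotypeArchetype]
) -> CohortPanel:
    """Draw a complete (no-missingness) labelled cohort panel.

    Each participant is assigned an archetype by weighted draw.  For each
    feature a latent Gaussian trajectory is drawn on the transformed scale,

        y* = a + b*t + c*t^2 + b0 + b1*t + b2*t^2 + eps,

    and the stored raw value is ``max(y*, 0)**2`` so that the square-root
    transform downstream recovers (approximately) Gaussian structure.
    """
    _check_weights(archetypes)
    features = archetypes[0].features
    for arch in archetypes[1:]:
        if arch.features != features:
            raise ValueError("all archetypes must define the same feature roster")

    ss = np.random.SeedSequence(config.seed)
    assign_rng, traj_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    n = config.n_participants
    weights = np.array([a.weight for a in archetypes])
    assignment = assign_rng.choice(len(archetypes), size=n, p=weights / weights.sum())

    t = config.visit_units
    design = np.column_stack([np.ones_like(t), t, t * t])  # (V, 3)
    n_visits = len(t)

    pids = np.arange(1, n + 1)
    rows: dict[str, np.ndarray] = {
        "pid": np.repeat(pids, n_visits),
        "visit_month": np.tile(np.asarray(config.visit_months), n),
    }
    values = {f: np.empty(n * n_visits) for f in features}

    for i, pid in enumerate(pids):
        arch = archetypes[assignment[i]]
        sl = slice(i * n_visits, (i + 1) * n_visits)
        for f in features:
            a, b, c = arch.trajectories[f]
            mean = design @ np.array([a, b, c])
            cov = np.asarray(arch.random_effect_cov[f], dtype=float)
            b_i = traj_rng.multivariate_normal(np.zeros(3), cov, method="svd")
            eps = traj_rng.normal(0.0, arch.residual_sd[f], size=n_visits)
            latent = mean + design @ b_i + eps
            values[f][sl] = np.maximum(latent, 0.0) ** 2

    data = pd.DataFrame({**rows, **{f: values[f] for f in features}})
    truth = pd.Series(
        [archetypes[j].label for j in assignment], index=pd.Index(pids, name="pid"),
        name="phenotype",
    )
    return CohortPanel(data=data, truth=truth)


def apply_missingness(panel: CohortPanel, config: CohortConfig) -> CohortPanel:
    """Delete visits and cells at the configured rates.

    Non-baseline visits are deleted independently at their per-visit rates;
    remaining feature cells are deleted independently at the item rate.
    Participants left with fewer than two observed visits are removed (count
    logged and stored on the returned panel).  Baseline is never deleted.
    """
    ss = np.random.SeedSequence((config.seed, 1))
    rng = np.random.default_rng(ss)
    data = panel.data.copy()
    features = panel.feature_names
    months = list(config.visit_months)
    baseline_month = months[0]

    # visit-level deletion
    keep = np.ones(len(data), dtype=bool)
    for month, rate in zip(months, config.miss_visit_rates):
        if month == baseline_month or rate == 0.0:
            continue
        at_visit = (data["visit_month"] == month).to_numpy()
        drop = rng.random(len(data)) < rate
        keep &= ~(at_visit & drop)
    data = data.loc[keep].reset_index(drop=True)

    # item-level deletion
    if config.item_miss_rate > 0 and features:
        mask = rng.random((len(data), len(features))) < config.item_miss_rate
        block = data[features].to_numpy(dtype=float)
        block[mask] = np.nan
        data[features] = block

    # drop participants with < 2 observed visits
    counts = data.groupby("pid").size()
    keep_pids = counts.index[counts >= 2]
    n_removed = int((counts < 2).sum())
    if n_removed:
        logger.info("apply_missingness: removed %d participants with < 2 visits", n_removed)
    data = data[data["pid"].isin(keep_pids)].reset_index(drop=True)

    truth = panel.truth
    if truth is not None:
        truth = truth.loc[truth.index.isin(data["pid"].unique())]
    return CohortPanel(data=data, truth=truth, n_removed=n_removed)


def simulate_baseline_covariates(panel: CohortPanel, config: CohortConfig) -> pd.DataFrame:
    """Draw baseline covariates keyed by pid, from phenotype-specific laws.

    Binary comorbidities are Bernoulli at the phenotype-specific prevalence;
    count covariates are Poisson; continuous covariates are Normal.
    """
    if panel.truth is None:
        raise ValueError("truth labels required to simulate baseline covariates")
    ss = np.random.SeedSequence((config.seed, 2))
    rng = np.random.default_rng(ss)

    pids = panel.truth.index.to_numpy()
    labels = panel.truth.to_numpy()
    phenotypes = sorted(np.unique(labels))
    # phenotype label -> position in prevalence tuples
    pos = {p: i for i, p in enumerate(phenotypes)}

    out = pd.DataFrame(index=pd.Index(pids, name="pid"))
    for name, prev in config.comorbidity_prevalence.items():
        if len(prev) < len(phenotypes):
            raise ValueError(f"comorbidity {name!r}: missing prevalence for some phenotype")
        p = np.array([prev[pos[l]] for l in labels])
        out[name] = (rng.random(len(pids)) < p).astype(int)
    for name, rates in config.count_rates.items():
        if len(rates) < len(phenotypes):
            raise ValueError(f"count covariate {name!r}: missing rate for some phenotype")
        lam = np.array([rates[pos[l]] for l in labels])
        out[name] = rng.poisson(lam)
    for name, params in config.continuous_params.items():
        if len(params) < len(phenotypes):
            raise ValueError(f"continuous covariate {name!r}: missing params for some phenotype")
        mu = np.array([params[pos[l]][0] for l in labels])
        sd = np.array([params[pos[l]][1] for l in labels])
        out[name] = rng.normal(mu, sd)
    return out.reset_index()


def _grouped_trajectories(
    cognitive: tuple[float, float, float],
    mood: tuple[float, float, float],
    function: tuple[float, float, float],
    features: Sequence[str] = DEFAULT_FEATURES,
) -> dict[str, tuple[float, float, float]]:
    traj = {}
    for f in features:
        if f.startswith("dds_"):
            traj[f] = cognitive
        elif f.startswith("bdi_"):
            traj[f] = mood
        else:
            traj[f] = function
    return traj


def default_archetypes(
    features: Sequence[str] = DEFAULT_FEATURES,
    weights: Sequence[float] = DEFAULT_WEIGHTS,
    intercept_sd: float = 0.15,
    slope_sd: float = 0.04,
    quad_sd: float = 0.012,
    residual_sd: float = 0.25,
) -> list[PhenotypeArchetype]:
    """Four well-separated archetypes with baseline severity monotone in label.

    Label 1 is healthiest and stable; 2 starts depressed/disabled and
    improves; 3 is severely depressed/disabled and worsens slightly; 4 is the
    most cognitively impaired and worsens.  Coefficients live on the
    square-root scale per visit unit.
    """
    patterns = [
        # (cognitive, mood, function) = (a, b, c) triples
        ((1.2, 0.0, 0.0), (1.2, 0.0, 0.0), (1.2, 0.0, 0.0)),
        ((2.0, 0.0, 0.0), (3.5, -0.50, 0.05), (3.2, -0.45, 0.05)),
        ((1.4, 0.0, 0.0), (4.2, 0.15, 0.0), (3.6, 0.12, 0.0)),
        ((4.2, 0.35, 0.0), (1.8, 0.0, 0.0), (2.4, 0.0, 0.0)),
    ]
    cov = np.diag([intercept_sd**2, slope_sd**2, quad_sd**2])
    archetypes = []
    for i, (w, (cog, mood, fun)) in enumerate(zip(weights, patterns), start=1):
        archetypes.append(
            PhenotypeArchetype(
                label=i,
                weight=float(w),
                trajectories=_grouped_trajectories(cog, mood, fun, features),
                random_effect_cov={f: cov for f in features},
                residual_sd={f: residual_sd for f in features},
            )
        )
    return archetypes
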