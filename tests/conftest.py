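import numpy as np
import pandas as pd
import pytest

from mlbpsp.synthetic_cohort import (
    CohortConfig,
    PhenotypeArchetype,
    apply_missingness,
    default_archetypes,
    simulate_cohort,
)
from mlbpsp.trajectory_features import default_feature_specs, extract_random_effects, fit_feature_lmm


def single_feature_archetype(
    label=1,
    weight=1.0,
    coeffs=(3.0, 0.0, 0.0),
    cov=None,
    sigma=0.3,
    feature="f",
):
    """One-archetype, one-feature helper for focused simulations."""
    cov = np.zeros((3, 3)) if cov is None else np.asarray(cov, dtype=float)
    return PhenotypeArchetype(
        label=label,
        weight=weight,
        trajectories={feature: tuple(coeffs)},
        random_effect_cov={feature: cov},
        residual_sd={feature: sigma},
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Complete 80-participant default-archetype cohort (no missingness)."""
    cfg = CohortConfig(n_participants=80, seed=11, item_miss_rate=0.0,
                       miss_visit_rates=(0.0, 0.0, 0.0, 0.0))
    return simulate_cohort(cfg, default_archetypes()), cfg


@pytest.fixture(scope="session")
def fitted_cohort():
    """Full-size separable cohort with missingness, fitted through step one.

    Session-scoped because the 17 mixed-model fits dominate suite runtime.
    Returns (panel, config, random-effects matrix).
    """
    cfg = CohortConfig(n_participants=506, seed=42)
    panel = apply_missingness(simulate_cohort(cfg, default_archetypes()), cfg)
    specs = default_feature_specs(panel.feature_names)
    fits = [fit_feature_lmm(panel, s) for s in specs]
    matrix = extract_random_effects(fits)
    return panel, cfg, fits, matrix


def expand_counts(count_table: dict) -> tuple[pd.Series, pd.Series]:
    """Turn {phenotype: (cases, n)} into aligned predictor/label Series."""
    xs, ys = [], []
    for ph, (cases, n) in count_table.items():
        xs += [1] * cases + [0] * (n - cases)
        ys += [ph] * n
    idx = pd.RangeIndex(len(xs))
    return pd.Series(xs, index=idx, name="predictor"), pd.Series(ys, index=idx, name="phenotype")
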