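"""Age residualization of tract FA.

FA declines roughly linearly with age over the adult range, so a
per-tract ordinary-least-squares regression on age is fitted and its
residuals (FA^r) are the feature entering all distance computations.
By default the regression is fitted on controls only — the normative
model should not absorb patient pathology — and applied to everyone;
fitting on the full cohort is available and the choice is recorded in
output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CONTROL, CohortTable

CONTROLS_ONLY = "controls_only"
ALL_SUBJECTS = "all_subjects"


class DegenerateDesignError(ValueError):
    """Age has no variance in the fit population."""


class SampleSizeError(ValueError):
    """Too few subjects for the requested fit."""


@dataclass(frozen=True)
class ResidualProfile:
    """One subject's age-residualized FA vector, tract order fixed."""

    subject_id: str
    fa_r: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "fa_r", np.asarray(self.fa_r, dtype=float))
        if not np.all(np.isfinite(self.fa_r)):
            raise ValueError(f"non-finite residual for subject {self.subject_id!r}")


@dataclass(frozen=True)
class AgeModel:
    """Per-tract linear age model: FA ≈ intercept + slope·age."""

    tracts: tuple[str, ...]
    intercepts: np.ndarray  # FA units
    slopes: np.ndarray  # FA units per year
    fit_population: str

    def predict(self, age: float | np.ndarray) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        return self.intercepts + np.outer(age, self.slopes).squeeze()

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"intercept": self.intercepts, "slope": self.slopes},
            index=pd.Index(self.tracts, name="tract"),
        ).to_csv(path, float_format="%.17g")


def fit_age_model(cohort: CohortTable, fit_population: str = CONTROLS_ONLY) -> AgeModel:
    """Fit the per-tract OLS age model on the chosen population.

    Requires at least 3 subjects and non-zero age variance in the fit
    population.
    """
    if fit_population == CONTROLS_ONLY:
        sub = cohort.data[cohort.data["group"] == CONTROL]
    elif fit_population == ALL_SUBJECTS:
        sub = cohort.data
    else:
        raise ValueError(f"unknown fit_population {fit_population!r}")
    if len(sub) < 3:
        raise SampleSizeError(
            f"age model needs >=3 subjects in {fit_population}, got {len(sub)}"
        )
    age = sub["age"].to_numpy(dtype=float)
    if np.ptp(age) == 0:
        raise DegenerateDesignError("age variance is zero in the fit population")
    X = np.column_stack([np.ones_like(age), age])
    Y = sub[cohort.tracts].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return AgeModel(tuple(cohort.tracts), beta[0].copy(), beta[1].copy(), fit_population)


def residualize_cohort(cohort: CohortTable, model: AgeModel) -> list[ResidualProfile]:
    """Subtract the fitted age trend from every subject's FA profile.

    The single fitted model is applied to controls and patients alike.
    """
    if tuple(cohort.tracts) != model.tracts:
        raise ValueError(
            "tract mismatch between cohort and age model: "
            f"{cohort.tracts} vs {list(model.tracts)}"
        )
    ages = cohort.ages.to_numpy(dtype=float)
    fa = cohort.fa.to_numpy(dtype=float)
    fitted = model.intercepts[None, :] + ages[:, None] * model.slopes[None, :]
    resid = fa - fitted
    return [
        ResidualProfile(sid, resid[i]) for i, sid in enumerate(cohort.subject_ids)
    ]


def residuals_frame(profiles: list[ResidualProfile], tracts) -> pd.DataFrame:
    """Stack residual profiles into a subjects x tracts DataFrame."""
    return pd.DataFrame(
        np.vstack([p.fa_r for p in profiles]),
        index=pd.Index([p.subject_id for p in profiles], name="subject_id"),
        columns=list(tracts),
    )
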