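"""Model/Results facade tying the pipeline together.

:class:`TractSeverityModel` is built from a cohort (or a DataFrame /
CSV file plus a column schema) and holds the analysis configuration;
``fit()`` runs age residualization and permutation-subsampled distance
scoring and returns a :class:`TractSeverityResults` carrying per-subject
scores, the cognitive composite when test scores are present, and the
evaluation methods (ROC/AUC discrimination, Spearman correlations,
plots, a text summary).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .cognition import PATIENTS_ONLY, CognitiveSummary, build_composite
from .covariance import SHRINKAGE
from .distances import SUBSAMPLE_SD, DistanceResult, results_frame, score_cohort
from .evaluation import (
    RocCurve,
    evaluate_correlations,
    evaluate_discrimination,
    robust_line,
    roc_auc,
)
from .io import CohortSchema, CohortTable, ResultTable, read_cohort
from .residualize import CONTROLS_ONLY, AgeModel, fit_age_model, residualize_cohort


class TractSeverityModel:
    """Normative multivariate severity model for a tract-FA cohort.

    Parameters
    ----------
    cohort
        Validated :class:`~tractnorm.io.CohortTable`.
    fit_population
        Population for the age regression (default controls only).
    covariance_method
        ``"shrinkage"`` (default) or ``"sample"``.
    z_sd
        SD convention for univariate |Z|: ``"subsample"`` (default,
        consistent with the permutation approach) or ``"pool"``.
    cognition_fit
        Subjects entering the composite PCA (default patients only).
    """

    def __init__(
        self,
        cohort: CohortTable,
        fit_population: str = CONTROLS_ONLY,
        covariance_method: str = SHRINKAGE,
        z_sd: str = SUBSAMPLE_SD,
        cognition_fit: str = PATIENTS_ONLY,
    ) -> None:
        self.cohort = cohort
        self.fit_population = fit_population
        self.covariance_method = covariance_method
        self.z_sd = z_sd
        self.cognition_fit = cognition_fit

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, schema: CohortSchema | Mapping | None = None, **kwargs
    ) -> "TractSeverityModel":
        """Build from a raw subjects-table DataFrame plus a schema."""
        from .io import cohort_from_raw

        return cls(cohort_from_raw(df, schema), **kwargs)

    @classmethod
    def from_csv(
        cls, path: str | Path, schema: CohortSchema | Mapping | None = None, **kwargs
    ) -> "TractSeverityModel":
        return cls(read_cohort(path, schema), **kwargs)

    def fit(
        self, subset_size: int = 25, n_perm: int = 1000, seed: int = 0
    ) -> "TractSeverityResults":
        """Run residualization and permutation-subsampled scoring."""
        cohort = self.cohort
        age_model = fit_age_model(cohort, self.fit_population)
        profiles = residualize_cohort(cohort, age_model)
        results = score_cohort(
            profiles,
            cohort.groups,
            subset_size=subset_size,
            n_perm=n_perm,
            seed=seed,
            method=self.covariance_method,
            z_sd=self.z_sd,
        )
        composite = None
        if cohort.cognition:
            composite = build_composite(
                cohort.data[cohort.cognition],
                fit_population=self.cognition_fit,
                groups=cohort.groups,
            )
        return TractSeverityResults(
            model=self,
            age_model=age_model,
            distance_results=results,
            composite=composite,
            subset_size=subset_size,
            n_perm=n_perm,
            seed=seed,
        )


@dataclass
class TractSeverityResults:
    """Fitted severity scores plus evaluation and reporting methods."""

    model: TractSeverityModel
    age_model: AgeModel
    distance_results: list[DistanceResult]
    composite: CognitiveSummary | None
    subset_size: int
    n_perm: int
    seed: int
    _scores: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def scores(self) -> pd.DataFrame:
        """Per-subject table: group, m_median, one z column per tract."""
        if self._scores is None:
            self._scores = results_frame(
                self.distance_results, self.model.cohort.tracts,
                self.model.cohort.groups,
            )
        return self._scores

    @property
    def metadata(self) -> dict:
        return {
            "software": f"tractnorm {__version__}",
            "subset_size": self.subset_size,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "covariance_method": self.model.covariance_method,
            "fit_population": self.model.fit_population,
            "z_sd": self.model.z_sd,
        }

    def scores_table(self) -> ResultTable:
        return ResultTable(self.scores, dict(self.metadata))

    def discrimination(self) -> ResultTable:
        """Per-tract univariate AUCs plus the multivariate M AUC."""
        return evaluate_discrimination(self.scores, self.model.cohort.tracts)

    def roc(self, measure: str = "M") -> RocCurve:
        col = "m_median" if measure == "M" else f"z_{measure}"
        return roc_auc(self.scores[col], self.scores["group"])

    def correlations(self) -> ResultTable:
        """Spearman of M and each |Z| against the cognitive composite."""
        if self.composite is None:
            raise ValueError("cohort has no cognitive scores")
        return evaluate_correlations(
            self.scores, self.composite.pc1_scores, self.model.cohort.tracts
        )

    def summary(self) -> str:
        """Human-readable analysis summary."""
        disc = self.discrimination()
        lines = [
            "Normative tract-FA severity model",
            "=" * 48,
            f"subjects:       {len(self.scores)} "
            f"({self.model.cohort.n_controls} controls, "
            f"{self.model.cohort.n_patients} patients)",
            f"tracts:         {len(self.model.cohort.tracts)}",
            f"subset size:    {self.subset_size}   permutations: {self.n_perm}",
            f"covariance:     {self.model.covariance_method}   "
            f"seed: {self.seed}",
            "-" * 48,
            f"AUC (multivariate M):      {disc.metadata['multivariate_auc']}",
            f"AUC (best univariate |Z|): {disc.metadata['best_univariate_auc']}"
            f"  [{disc.metadata['best_univariate_tract']}]",
        ]
        if self.composite is not None:
            corr = self.correlations()
            lines += [
                "-" * 48,
                f"cognitive composite: PC1 explains "
                f"{100 * self.composite.variance_explained_pc1:.1f}% of variance",
                f"Spearman rho(M, composite): {corr.metadata['m_rho']}"
                f"  (p = {corr.metadata['m_p_value']})",
            ]
        lines.append("=" * 48)
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------

    def plot_roc(self, ax=None):
        """ROC curves for M and the best univariate tract."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        disc = self.discrimination()
        best = disc.metadata["best_univariate_tract"]
        for measure, style in ((best, "--"), ("M", "-")):
            curve = self.roc(measure)
            ax.plot(curve.fpr, curve.tpr, style,
                    label=f"{measure} (AUC {curve.auc:.2f})")
        ax.plot([0, 1], [0, 1], ":", color="grey", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(loc="lower right")
        return ax

    def plot_correlation(self, ax=None):
        """Patients' M vs cognitive composite with a bisquare fit line."""
        import matplotlib.pyplot as plt

        if self.composite is None:
            raise ValueError("cohort has no cognitive scores")
        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        pats = self.scores[self.scores["group"] == "patient"]
        common = pats.index.intersection(self.composite.pc1_scores.index)
        x = pats.loc[common, "m_median"].to_numpy()
        y = self.composite.pc1_scores.loc[common].to_numpy()
        slope, intercept, _ = robust_line(x, y)
        ax.scatter(x, y, s=18)
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, slope * xs + intercept, "r-", lw=1.2, label="bisquare fit")
        ax.set_xlabel("multivariate distance M")
        ax.set_ylabel("cognitive composite (higher = poorer)")
        ax.legend()
        return ax
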