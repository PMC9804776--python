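"""Publication-bias diagnostics for multilevel meta-analysis.

Two complementary tests, both multilevel variants of Egger's regression
that keep the study and species random intercepts (and an estimate-level
residual) so that non-independence among effect sizes does not masquerade
as funnel asymmetry:

* outcome-reporting bias — regress y_i on its sampling variance v_i; a
  significant slope indicates funnel asymmetry (small, imprecise studies
  systematically reporting larger effects);
* time-lag bias — regress y_i on (centred) publication year; a negative
  significant slope is the decline effect.

Funnel-plot coordinates come from the marginal residuals of the full
moderator meta-regression, which strip the moderator structure while
retaining the heterogeneity the funnel is meant to display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .effects_io import EffectSizeRecord
from .mlmeta import (
    FitResult,
    ModelSpec,
    RandomTermStruct,
    _grouping_matrix,
    fit_reml,
    wald_tests,
)

__all__ = ["BiasTestResult", "funnel_data", "egger_test", "time_lag_test"]

SUBSETS = ("all", "TRF", "qPCR")
_TRF_METHODS = {"TRF_southern", "TRF_ingel"}


@dataclass
class BiasTestResult:
    subset: str
    predictor: str
    slope: float
    slope_se: float
    z: float
    p: float
    intercept: float
    components: dict[str, float]
    n: int
    warning: str | None = None

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p < alpha

    def to_dict(self) -> dict:
        return {
            "subset": self.subset,
            "predictor": self.predictor,
            "slope": self.slope,
            "slope_se": self.slope_se,
            "z": self.z,
            "p": self.p,
            "intercept": self.intercept,
            "components": self.components,
            "n": self.n,
            "warning": self.warning,
        }


def funnel_data(fit: FitResult, records: Sequence[EffectSizeRecord]) -> pd.DataFrame:
    """Residual-vs-precision coordinates for a funnel plot.

    Marginal residuals y - X beta-hat and precision 1/se per record; the
    laboratory method is carried along so TRF and qPCR points can be
    distinguished.
    """
    if len(records) != fit.spec.n:
        raise ValueError("records do not match the fitted model")
    resid = fit.residuals
    return pd.DataFrame(
        {
            "estimate_id": [r.estimate_id for r in records],
            "residual": resid,
            "precision": 1.0 / np.sqrt(fit.spec.v),
            "laboratory_method": [r.laboratory_method for r in records],
        }
    )


def _bias_model(
    records: Sequence[EffectSizeRecord], predictor: np.ndarray, name: str
) -> ModelSpec:
    n = len(records)
    y = np.array([r.h2 for r in records])
    v = np.array([r.sampling_variance for r in records])
    X = np.column_stack([np.ones(n), predictor])
    Zu, _ = _grouping_matrix([r.study_id for r in records])
    Zs, _ = _grouping_matrix([r.species for r in records])
    return ModelSpec(
        y=y,
        v=v,
        X=X,
        fixed_names=["intercept", name],
        random_terms=[
            RandomTermStruct("study", Zu @ Zu.T),
            RandomTermStruct("species", Zs @ Zs.T),
            RandomTermStruct("estimate", np.eye(n)),
        ],
        estimate_ids=[r.estimate_id for r in records],
    )


def _filter_subset(
    records: Sequence[EffectSizeRecord], subset: str
) -> list[EffectSizeRecord]:
    if subset == "all":
        return list(records)
    if subset == "TRF":
        return [r for r in records if r.laboratory_method in _TRF_METHODS]
    if subset == "qPCR":
        return [r for r in records if r.laboratory_method == "qPCR"]
    raise ValueError(f"unknown subset {subset!r}; expected one of {SUBSETS}")


def egger_test(
    records: Sequence[EffectSizeRecord],
    subset: str = "all",
    predictor: str = "v",
) -> BiasTestResult:
    """Multilevel Egger regression of effect size on sampling variance.

    ``predictor='se'`` swaps the regressor to the standard error, a
    variant sometimes preferred; the default follows the sampling-variance
    formulation.  The model keeps study and species random intercepts and
    is weighted by the known v_i.
    """
    sub = _filter_subset(records, subset)
    if not sub:
        raise ValueError(f"subset {subset!r} is empty")
    note = None
    if len(sub) < 10:
        note = f"only {len(sub)} records in subset {subset!r}; test is underpowered"
        warnings.warn(note, stacklevel=2)
    if predictor == "v":
        x = np.array([r.sampling_variance for r in sub])
    elif predictor == "se":
        x = np.array([r.se for r in sub])
    else:
        raise ValueError("predictor must be 'v' or 'se'")
    fit = fit_reml(_bias_model(sub, x, predictor))
    return _result_from_fit(fit, subset, predictor, note)


def time_lag_test(records: Sequence[EffectSizeRecord]) -> BiasTestResult:
    """Decline-effect test: effect size regressed on publication year.

    Years are centred at their mean so the intercept stays interpretable
    as the mean effect at the average publication date; the slope is
    unaffected by centring.
    """
    years = np.array([float(r.publication_year) for r in records])
    if len(np.unique(years)) < 2:
        raise ValueError("publication years are all identical; no time-lag test")
    centred = years - years.mean()
    fit = fit_reml(_bias_model(list(records), centred, "year_centred"))
    return _result_from_fit(fit, "all", "year", None)


def _result_from_fit(
    fit: FitResult, subset: str, predictor: str, note: str | None
) -> BiasTestResult:
    table = wald_tests(fit)
    row = table.iloc[1]
    return BiasTestResult(
        subset=subset,
        predictor=predictor,
        slope=float(row["estimate"]),
        slope_se=float(row["se"]),
        z=float(row["z"]),
        p=float(row["p"]),
        intercept=float(table.iloc[0]["estimate"]),
        components=dict(fit.components),
        n=fit.spec.n,
        warning=note,
    )
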