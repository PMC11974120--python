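"""End-to-end analysis of a cohort in memory.

Chains the stages: preprocessing -> window-level biomarkers ->
within-subject normalization -> contact means -> group comparisons ->
two-level outcome model. Each stage is also available individually from
its own module; this is the convenience layer used by the command-line
pipeline, the tests and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .features import (
    ApEnParams,
    compute_features,
    contact_average,
    zscore_within_subject,
)
from .predict import OutcomeModel, OutcomeResults, SplitPlan
from .preprocess import TOTAL_S_DEFAULT, WINDOW_S_DEFAULT, preprocess_recording
from .simulate import SyntheticCohort
from .stats import run_comparisons

__all__ = ["cohort_features", "analyze_cohort", "CohortAnalysis"]


def cohort_features(
    cohort: SyntheticCohort,
    window_s: float = WINDOW_S_DEFAULT,
    total_s: float = TOTAL_S_DEFAULT,
    apen_params: ApEnParams = ApEnParams(),
    bad_spans: dict[tuple[str, str], list] | None = None,
) -> pd.DataFrame:
    """Raw window-level feature table for every recording in a cohort.

    ``bad_spans`` optionally maps (patient_id, period) to artifact span
    lists. Post-operative TC channels are removed inside preprocessing.
    """
    tables = []
    for (pid, period), rec in sorted(cohort.recordings.items()):
        spans = (bad_spans or {}).get((pid, period))
        windowed = preprocess_recording(
            rec, cohort.contacts, bad_spans=spans,
            window_s=window_s, total_s=total_s)
        tables.append(compute_features(windowed, cohort.contacts, pid,
                                       period, apen_params))
    out = pd.concat(tables, ignore_index=True)
    out.attrs["normalized"] = False
    return out


@dataclass
class CohortAnalysis:
    """Everything the pipeline produces for one cohort."""

    features: pd.DataFrame  # window-level, normalized
    contact_means: pd.DataFrame
    comparisons: pd.DataFrame
    outcome: OutcomeResults | None


def analyze_cohort(
    cohort: SyntheticCohort,
    window_s: float = WINDOW_S_DEFAULT,
    total_s: float = TOTAL_S_DEFAULT,
    apen_params: ApEnParams = ApEnParams(),
    plan: SplitPlan | None = None,
    grid: list[dict] | None = None,
    folds: int = 25,
    seed: int = 0,
    fit_outcome: bool = True,
    bad_spans: dict[tuple[str, str], list] | None = None,
) -> CohortAnalysis:
    """Full pipeline on an in-memory cohort; deterministic under ``seed``."""
    raw = cohort_features(cohort, window_s=window_s, total_s=total_s,
                          apen_params=apen_params, bad_spans=bad_spans)
    normalized = zscore_within_subject(raw)
    means = contact_average(normalized)
    comparisons = run_comparisons(means, cohort.contacts, cohort.outcomes)
    outcome = None
    if fit_outcome:
        model = OutcomeModel.from_contact_means(
            means, cohort.contacts, cohort.outcomes,
            plan=plan or SplitPlan(seed=seed), grid=grid, folds=folds)
        outcome = model.fit(seed=seed)
    return CohortAnalysis(features=normalized, contact_means=means,
                          comparisons=comparisons, outcome=outcome)
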