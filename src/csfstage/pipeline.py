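"""Cohort table -> z-scores -> abnormality mixtures -> sequence model.

The full fit interleaves sequence estimation with mixture refinement:
marginal per-biomarker two-Gaussian fits are weakly identified where the
components overlap, and the residual density error is systematic enough for
cross-validated comparisons to hallucinate extra subtypes.  Re-estimating
the components from the fitted model's own abnormality posteriors (which
pool information across biomarkers through the subject's stage) removes
most of that error; the sequence fit is warm-started between rounds so
structure is tracked, not rediscovered.

Fitting and staging are split so a model fit on one cohort can stage a
second cohort without refitting (cross-cohort transfer)."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .ebm import (SamplerSettings, SequenceModel, StageAssignment,
                  event_abnormality_posterior, fit_sequences, refit_sequences,
                  stage_subjects)
from .panel import BiomarkerPanel
from .preprocess import (EventProbabilityMatrix, MixtureModel, ZScoreModel,
                         apply_zscore, event_probabilities,
                         fit_event_mixtures, fit_reference_zscore,
                         refine_event_mixtures, select_reference)

DEFAULT_REFINE_ROUNDS = 5


def baseline_rows(cohort: pd.DataFrame) -> pd.DataFrame:
    """First visit per subject."""
    if "visit_time" not in cohort.columns:
        return cohort
    idx = cohort.groupby("subject_id")["visit_time"].idxmin()
    return cohort.loc[sorted(idx)]


@dataclass
class FittedPipeline:
    """Frozen preprocessing plus the fitted sequence model."""

    panel: BiomarkerPanel
    zscore: ZScoreModel
    mixtures: MixtureModel
    model: SequenceModel


def compute_events(
    cohort: pd.DataFrame,
    panel: BiomarkerPanel,
    zscore: ZScoreModel,
    mixtures: MixtureModel,
) -> EventProbabilityMatrix:
    z = apply_zscore(cohort, zscore)[list(panel.names)]
    return event_probabilities(z, mixtures,
                               subject_ids=cohort["subject_id"].to_numpy())


def fit_pipeline(
    cohort: pd.DataFrame,
    panel: BiomarkerPanel,
    n_subtypes: int = 1,
    settings: SamplerSettings | None = None,
    seed: int = 0,
    zscore: ZScoreModel | None = None,
    mixtures: MixtureModel | None = None,
    refine_rounds: int = DEFAULT_REFINE_ROUNDS,
) -> FittedPipeline:
    """Fit z-scoring, abnormality mixtures and the event ordering.

    After an initial marginal mixture fit and sequence fit, the mixtures
    are re-estimated ``refine_rounds`` times from the model's abnormality
    posteriors, warm-starting the sequence fit each round (MCMC samples are
    refreshed on the final round).  Pre-fitted ``zscore``/``mixtures``
    (e.g. from another cohort) are reused when given, skipping refinement.
    """
    base = baseline_rows(cohort)
    if zscore is None:
        zscore = fit_reference_zscore(base, panel)
    z = apply_zscore(base, zscore)[list(panel.names)]
    ref = select_reference(base).to_numpy()
    transferred = mixtures is not None
    if mixtures is None:
        mixtures = fit_event_mixtures(z, reference_mask=ref)
    events = compute_events(base, panel, zscore, mixtures)
    model = fit_sequences(events, n_subtypes=n_subtypes, settings=settings,
                          seed=seed)
    if not transferred and refine_rounds > 0:
        complete = z.notna().all(axis=1).to_numpy()
        zc, refc = z.loc[complete], ref[complete]
        for r in range(refine_rounds):
            posterior = event_abnormality_posterior(events, model)
            mixtures = refine_event_mixtures(zc, posterior,
                                             reference_mask=refc)
            events = compute_events(base, panel, zscore, mixtures)
            model = refit_sequences(
                events, model, settings=settings, seed=seed + r + 1,
                sample=(r == refine_rounds - 1),
            )
    return FittedPipeline(panel, zscore, mixtures, model)


def stage_cohort(cohort: pd.DataFrame, fitted: FittedPipeline) -> StageAssignment:
    """Stage (possibly new) subjects under a fitted pipeline."""
    events = compute_events(cohort, fitted.panel, fitted.zscore,
                            fitted.mixtures)
    return stage_subjects(events, fitted.model)
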