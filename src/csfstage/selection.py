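"""Cross-validated model comparison.

CVIC (cross-validation information criterion) is -2 times the summed
held-out log-likelihood across folds; lower is better.  It drives both the
subtype-count choice (smallest count whose CVIC and held-out log-likelihood
are within tolerance of the best) and the iterative biomarker-subset
optimization (enumerate droppable-marker subsets, keep the panel with the
minimal CVIC).

All preprocessing (reference z-scoring and abnormality mixtures) is refit
inside each training fold so held-out subjects never influence the fit; a
``global_mixtures`` switch reproduces the alternative convention of fitting
mixtures once on the full sample.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .ebm import SamplerSettings, dataset_loglik_posterior, stage_subjects
from .panel import BiomarkerPanel
from .pipeline import (DEFAULT_REFINE_ROUNDS, baseline_rows, compute_events,
                       fit_pipeline)

logger = logging.getLogger(__name__)

#: deviance-scale slack under which two candidate fits count as "similar"
DELTA_CVIC = 6.0


@dataclass
class CVResult:
    """Per-fold held-out log-likelihoods for one candidate model."""

    label: str
    n_subtypes: int
    fold_logliks: list[float]
    seed: int
    fold_subjects: list[np.ndarray] = field(default_factory=list)
    fold_orderings: list[list[list[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.fold_logliks) < 2:
            raise ValueError("need >= 2 folds")
        if not np.isfinite(self.cvic):
            raise ValueError("CVIC must be finite")
        if self.fold_subjects:
            all_ids = np.concatenate(self.fold_subjects)
            if len(all_ids) != len(set(all_ids)):
                raise ValueError("folds must partition subjects")

    @property
    def cvic(self) -> float:
        return -2.0 * float(np.sum(self.fold_logliks))

    @property
    def median_loglik(self) -> float:
        return float(np.median(self.fold_logliks))


def _fold_seed(seed: int, fold: int) -> int:
    return int((seed * 1009 + fold) % (2**31 - 1))


def cross_validate(
    cohort: pd.DataFrame,
    panel: BiomarkerPanel,
    n_subtypes: int,
    k_folds: int = 10,
    seed: int = 0,
    settings: SamplerSettings | None = None,
    global_mixtures: bool = False,
    refine_rounds: int = DEFAULT_REFINE_ROUNDS,
    label: str | None = None,
    fold_assignments: list | None = None,
) -> CVResult:
    """K-fold out-of-sample log-likelihood of one candidate model.

    Folds are stratified by the MAP stage of a preliminary greedy full-data
    fit, so every fold spans the disease continuum.  Within each fold the
    whole pipeline (z-scoring, mixtures with refinement, sequences) is
    refit on the training subjects; held-out log-likelihood is averaged
    over the training fit's ordering posterior, so candidate subtype counts
    are compared on the same footing.  Deterministic given ``seed``.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if settings is None:
        settings = SamplerSettings()
    base = baseline_rows(cohort).reset_index(drop=True)

    pre = None
    if fold_assignments is not None:
        splits = fold_assignments
    else:
        # preliminary full-data fit (greedy only) for stage stratification
        pre_settings = SamplerSettings(
            n_startpoints=min(8, settings.n_startpoints), mcmc_iters=0,
            em_tol=settings.em_tol, em_max_iter=settings.em_max_iter,
            n_split_trials=1,
        )
        pre = fit_pipeline(base, panel, 1, pre_settings,
                           seed=_fold_seed(seed, 999), refine_rounds=0)
        events_all = compute_events(base, panel, pre.zscore, pre.mixtures)
        strata = stage_subjects(events_all, pre.model).stages

        skf = StratifiedKFold(n_splits=k_folds, shuffle=True,
                              random_state=seed)
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore",
                                    message="The least populated class")
            splits = list(skf.split(np.zeros(len(base)), strata))
    fold_lls, fold_subjects, fold_orderings = [], [], []
    for fold, (train_idx, test_idx) in enumerate(splits):
        if len(test_idx) < 10 or len(train_idx) < 10:
            raise ValueError(
                f"fold {fold} has fewer than 10 subjects "
                f"(train {len(train_idx)}, test {len(test_idx)})"
            )
        train, test = base.iloc[train_idx], base.iloc[test_idx]
        if global_mixtures and pre is None:
            raise ValueError(
                "global_mixtures requires stratified folds (omit "
                "fold_assignments)"
            )
        fitted = fit_pipeline(
            train, panel, n_subtypes, settings, seed=_fold_seed(seed, fold),
            mixtures=pre.mixtures if global_mixtures else None,
            refine_rounds=refine_rounds,
        )
        events_test = compute_events(test, panel, fitted.zscore,
                                     fitted.mixtures)
        fold_lls.append(dataset_loglik_posterior(events_test, fitted.model))
        fold_subjects.append(test["subject_id"].to_numpy())
        fold_orderings.append(
            [fitted.model.ordering_names(c)
             for c in range(fitted.model.n_subtypes)]
        )
    return CVResult(
        label if label is not None else str(n_subtypes),
        n_subtypes, fold_lls, seed, fold_subjects, fold_orderings,
    )


def select_n_subtypes(results: list[CVResult], tol: float = DELTA_CVIC) -> int:
    """The minimal subtype count whose fit is as good as the best.

    Rule: the smallest count whose CVIC is within ``tol`` of the minimum and
    whose median held-out log-likelihood is not worse than any larger
    candidate's by more than ``tol / 2`` (the same slack expressed on the
    log-likelihood rather than deviance scale).  Falls back to the CVIC
    argmin if no candidate satisfies both clauses.
    """
    if not results:
        raise ValueError("no candidate results")
    results = sorted(results, key=lambda r: r.n_subtypes)
    counts = [r.n_subtypes for r in results]
    if counts != list(range(1, len(counts) + 1)):
        raise ValueError("results must cover consecutive subtype counts from 1")
    cvics = np.array([r.cvic for r in results])
    medians = np.array([r.median_loglik for r in results])
    min_cvic = cvics.min()
    for i, r in enumerate(results):
        if cvics[i] > min_cvic + tol:
            continue
        larger = medians[i + 1:]
        if larger.size and medians[i] < larger.max() - tol / 2.0:
            continue
        return r.n_subtypes
    return results[int(cvics.argmin())].n_subtypes


def optimize_biomarker_set(
    cohort: pd.DataFrame,
    full_panel: BiomarkerPanel,
    removable: list[str] | tuple[str, ...],
    k_folds: int = 10,
    seed: int = 0,
    settings: SamplerSettings | None = None,
    refine_rounds: int = DEFAULT_REFINE_ROUNDS,
) -> tuple[BiomarkerPanel, pd.DataFrame]:
    """Enumerate droppable-marker subsets and pick the minimal-CVIC panel.

    All 2^len(removable) subsets (including dropping none) are compared with
    a one-subtype cross-validated fit; subsets leaving fewer than two
    biomarkers are skipped with a warning.  Returns the winning panel and
    the full comparison table.
    """
    removable = list(removable)
    if not removable:
        raise ValueError("removable must name at least one biomarker")
    unknown = [m for m in removable if m not in full_panel.names]
    if unknown:
        raise KeyError(f"removable markers not in panel: {unknown}")
    rows, panels = [], {}
    for r in range(len(removable) + 1):
        for drop in itertools.combinations(removable, r):
            candidate = full_panel.drop(list(drop))
            label = "drop:" + (",".join(drop) if drop else "none")
            if len(candidate) < 2:
                warnings.warn(f"{label}: fewer than 2 biomarkers left; skipped")
                continue
            res = cross_validate(
                cohort, candidate, n_subtypes=1, k_folds=k_folds, seed=seed,
                settings=settings, refine_rounds=refine_rounds, label=label,
            )
            panels[label] = candidate
            rows.append(
                {
                    "candidate": label,
                    "n_biomarkers": len(candidate),
                    "cvic": res.cvic,
                    "median_loglik": res.median_loglik,
                }
            )
            logger.info("%s: CVIC %.2f", label, res.cvic)
    table = pd.DataFrame(rows)
    best_label = table.loc[table["cvic"].idxmin(), "candidate"]
    return panels[best_label], table
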