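"""Downstream staging-utility statistics.

Everything that turns a fitted staging model into evidence of usefulness:
stage-wise biomarker summaries with contiguous-stage rank contrasts,
ROC/Youden prediction of dichotomous PET status, proportional-odds
prediction of ordinal outcomes with a concordance index, per-subject
longitudinal slopes, baseline-to-follow-up stage transition stability, and
stage-stratified Kaplan-Meier / Cox survival analysis of clinical
progression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .ebm import StageAssignment

DEFAULT_N_BOOT = 2000
RIDGE_PENALTY = 1e-4


# ---------------------------------------------------------------------------
# stage-wise summaries and contrasts
# ---------------------------------------------------------------------------

@dataclass
class StageGroupSummary:
    """Per-stage descriptives plus FDR-adjusted contiguous-stage contrasts."""

    summary: pd.DataFrame  # stage, n, mean, sd, trend
    contrasts: pd.DataFrame  # stage_a, stage_b, p, q

    def __post_init__(self) -> None:
        c = self.contrasts
        if len(c) and np.any(c["q"].to_numpy() < c["p"].to_numpy() - 1e-12):
            raise ValueError("q-values may not fall below p-values")


def stage_trajectory(
    values,
    stages,
    span: float = 0.75,
) -> StageGroupSummary:
    """Stage-wise mean/sd, a locally weighted linear (tricube) trend over
    stage, and two-sided rank-sum contrasts between contiguous stages with
    Benjamini-Hochberg adjustment."""
    values = np.asarray(values, float)
    stages = np.asarray(stages, int)
    ok = np.isfinite(values)
    values, stages = values[ok], stages[ok]
    if stages.min() < 0:
        raise ValueError("stages must be non-negative")
    occupied = np.unique(stages)

    smooth = lowess(values, stages.astype(float), frac=span, return_sorted=True)
    trend = {
        s: float(np.mean(smooth[smooth[:, 0] == s, 1])) for s in occupied
    }

    rows = []
    for s in occupied:
        v = values[stages == s]
        rows.append(
            {
                "stage": int(s),
                "n": len(v),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan,
                "trend": trend[int(s)],
            }
        )
    summary = pd.DataFrame(rows)

    pairs, pvals = [], []
    for a, b in zip(occupied[:-1], occupied[1:]):
        if b != a + 1:
            continue
        x, y = values[stages == a], values[stages == b]
        if len(x) < 2 or len(y) < 2:
            warnings.warn(f"contrast {a}-{b} skipped: a group has n < 2")
            continue
        if np.ptp(np.concatenate([x, y])) == 0:
            p = 1.0
        else:
            p = float(mannwhitneyu(x, y, alternative="two-sided").pvalue)
        pairs.append((int(a), int(b)))
        pvals.append(p)
    if pvals:
        q = multipletests(pvals, method="fdr_bh")[1]
    else:
        q = []
    contrasts = pd.DataFrame(
        [
            {"stage_a": a, "stage_b": b, "p": p, "q": qq}
            for (a, b), p, qq in zip(pairs, pvals, q)
        ],
        columns=["stage_a", "stage_b", "p", "q"],
    )
    return StageGroupSummary(summary, contrasts)


# ---------------------------------------------------------------------------
# ROC / Youden stage cutoff
# ---------------------------------------------------------------------------

@dataclass
class CutoffResult:
    """AUC with bootstrap CI and the Youden-optimal stage cutoff."""

    auc: float
    auc_ci: tuple[float, float]
    cutoff: int
    sensitivity: float
    specificity: float
    n_boot: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")
        lo, hi = self.auc_ci
        if not lo <= self.auc <= hi:
            raise ValueError("CI must contain the point estimate")


def _youden_cutoff(stages: np.ndarray, outcome: np.ndarray):
    """Stage threshold t (positive if stage >= t) maximizing
    sensitivity + specificity - 1; ties go to the lowest threshold."""
    best = (None, -np.inf, np.nan, np.nan)
    for t in np.unique(stages):
        pred = stages >= t
        sens = float(pred[outcome == 1].mean())
        spec = float((~pred[outcome == 0]).mean())
        j = sens + spec - 1.0
        if j > best[1] + 1e-12:
            best = (int(t), j, sens, spec)
    return best[0], best[2], best[3]


def roc_optimal_stage(
    stages,
    binary_outcome,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> CutoffResult:
    """AUC of the ordinal stage predictor and its Youden-optimal cutoff.

    The AUC uses the rank (Mann-Whitney) formulation, so stage ties
    contribute 1/2; the CI is a seeded percentile bootstrap.
    """
    stages = np.asarray(stages, int)
    outcome = np.asarray(binary_outcome, int)
    classes = np.unique(outcome)
    if len(classes) < 2:
        raise ValueError("both outcome classes must be present")
    auc = float(roc_auc_score(outcome, stages))
    cutoff, sens, spec = _youden_cutoff(stages, outcome)

    rng = np.random.default_rng(seed)
    boots = []
    n = len(stages)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        o = outcome[idx]
        if o.min() == o.max():
            continue
        boots.append(roc_auc_score(o, stages[idx]))
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
        ci = (min(float(lo), auc), max(float(hi), auc))
    else:
        ci = (auc, auc)
    return CutoffResult(auc, ci, cutoff, sens, spec, n_boot)


# ---------------------------------------------------------------------------
# ordinal (proportional-odds) prediction
# ---------------------------------------------------------------------------

@dataclass
class OrdinalPrediction:
    """Proportional-odds fit of an ordinal outcome on stage."""

    categories: list
    coef: float
    cutpoints: np.ndarray
    stage_probs: pd.DataFrame  # index: stage, columns: categories
    modal_category: dict[int, object]
    c_index: float
    c_index_ci: tuple[float, float]
    separation_flag: bool = False

    def __post_init__(self) -> None:
        if not np.allclose(self.stage_probs.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("per-stage category probabilities must sum to 1")
        if not 0.0 <= self.c_index <= 1.0:
            raise ValueError("c-index must lie in [0, 1]")


def concordance_index(predictor, ordinal_outcome) -> float:
    """Concordance over all usable (differently-ranked outcome) pairs;
    predictor ties count 1/2."""
    x = np.asarray(predictor, float)
    y = np.asarray(ordinal_outcome)
    codes = pd.Categorical(y, ordered=True).codes.astype(float)
    conc = ties = usable = 0.0
    for a in np.unique(codes):
        xa = x[codes == a]
        xb = x[codes > a]
        if not len(xb):
            continue
        usable += len(xa) * len(xb)
        conc += (xa[:, None] < xb[None, :]).sum()
        ties += (xa[:, None] == xb[None, :]).sum()
    if usable == 0:
        raise ValueError("no usable pairs: outcome has a single category")
    return float((conc + 0.5 * ties) / usable)


def _cumlogit_nll(params, x, codes, n_cat, ridge):
    beta = params[0]
    cuts = np.concatenate([[params[1]], params[1] + np.cumsum(np.exp(params[2:]))])
    eta = beta * x
    # P(y <= j) = expit(cut_j - eta)
    cum = expit(cuts[None, :] - eta[:, None])
    cum = np.concatenate(
        [np.zeros((len(x), 1)), cum, np.ones((len(x), 1))], axis=1
    )
    probs = np.clip(np.diff(cum, axis=1), 1e-12, 1.0)
    nll = -np.log(probs[np.arange(len(x)), codes]).sum()
    return nll + ridge * beta**2


def _fit_cumlogit(x, codes, n_cat, ridge=0.0):
    start = np.concatenate(
        [[0.5], [float(np.median(x))], np.zeros(n_cat - 2)]
    )
    res = minimize(_cumlogit_nll, start, args=(x, codes, n_cat, ridge),
                   method="BFGS")
    beta = float(res.x[0])
    cuts = np.concatenate(
        [[res.x[1]], res.x[1] + np.cumsum(np.exp(res.x[2:]))]
    )
    return beta, cuts, res


def ordinal_prediction(
    stages,
    ordinal_outcome,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    categories: list | None = None,
) -> OrdinalPrediction:
    """Cumulative-logit proportional-odds model with stage as the sole
    predictor, per-stage predicted category probabilities, and a bootstrap
    CI for the concordance index.

    Complete separation (clean synthetic data) inflates the ML coefficient
    without bound; it is detected and handled with a small ridge penalty,
    flagged in the result.
    """
    stages = np.asarray(stages, float)
    cat = pd.Categorical(ordinal_outcome, categories=categories, ordered=True)
    codes = cat.codes.astype(int)
    if np.any(codes < 0):
        raise ValueError("outcome contains values outside the category list")
    levels = list(cat.categories)
    counts = np.bincount(codes, minlength=len(levels))
    present = counts > 0
    if present.sum() < 2:
        raise ValueError("need >= 2 ordered outcome categories")
    if np.any(counts[present] < 5):
        raise ValueError(
            "each present outcome category needs >= 5 subjects; counts "
            f"{dict(zip(levels, counts))}"
        )
    levels = [l for l, keep in zip(levels, present) if keep]
    codes = pd.Categorical(
        np.asarray(cat)[codes >= 0], categories=levels, ordered=True
    ).codes.astype(int)
    n_cat = len(levels)

    beta, cuts, res = _fit_cumlogit(stages, codes, n_cat, ridge=0.0)
    separated = (not res.success) or abs(beta) > 15.0
    if separated:
        beta, cuts, res = _fit_cumlogit(stages, codes, n_cat,
                                        ridge=RIDGE_PENALTY)
        if not res.success and np.linalg.norm(res.jac) > 1e-3:
            raise RuntimeError(
                "proportional-odds fit did not converge; "
                f"gradient norm {np.linalg.norm(res.jac):.3g}"
            )

    uniq = np.unique(stages).astype(int)
    cum = expit(cuts[None, :] - beta * uniq[:, None])
    cum = np.concatenate(
        [np.zeros((len(uniq), 1)), cum, np.ones((len(uniq), 1))], axis=1
    )
    probs = np.diff(cum, axis=1)
    stage_probs = pd.DataFrame(probs, index=uniq, columns=levels)
    modal = {int(s): stage_probs.loc[s].idxmax() for s in uniq}

    c = concordance_index(stages, codes)
    rng = np.random.default_rng(seed)
    boots = []
    n = len(stages)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if len(np.unique(codes[idx])) < 2:
            continue
        boots.append(concordance_index(stages[idx], codes[idx]))
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
        ci = (min(float(lo), c), max(float(hi), c))
    else:
        ci = (c, c)
    return OrdinalPrediction(levels, beta, cuts, stage_probs, modal, c, ci,
                             separation_flag=bool(separated))


# ---------------------------------------------------------------------------
# per-subject longitudinal slopes
# ---------------------------------------------------------------------------

def subject_slopes(
    long_df: pd.DataFrame,
    subject_col: str = "subject_id",
    time_col: str = "time",
    value_col: str = "value",
) -> pd.DataFrame:
    """Ordinary least-squares slope of value on time, per subject.

    Subjects with fewer than two visits or no time spread are excluded
    (count reported via warning log)."""
    rows, excluded = [], 0
    for sid, g in long_df.groupby(subject_col, sort=False):
        t = g[time_col].to_numpy(float)
        v = g[value_col].to_numpy(float)
        ok = np.isfinite(t) & np.isfinite(v)
        t, v = t[ok], v[ok]
        if len(t) < 2 or np.ptp(t) == 0:
            excluded += 1
            continue
        slope = float(np.polyfit(t, v, 1)[0])
        rows.append({subject_col: sid, "slope": slope, "n_visits": len(t)})
    if excluded:
        warnings.warn(f"subject_slopes: excluded {excluded} subject(s) with "
                      "fewer than 2 usable visits")
    return pd.DataFrame(rows, columns=[subject_col, "slope", "n_visits"])


# ---------------------------------------------------------------------------
# stage-transition stability
# ---------------------------------------------------------------------------

@dataclass
class TransitionMatrix:
    """Baseline-stage x follow-up-stage counts with stability percentages."""

    counts: np.ndarray
    pct_stable: float
    pct_progressed: float
    pct_regressed: float
    pct_progressed_one_stage: float

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    def __post_init__(self) -> None:
        total = self.pct_stable + self.pct_progressed + self.pct_regressed
        if abs(total - 100.0) > 1e-9:
            raise ValueError("stability percentages must sum to 100")


def _stage_series(obj) -> pd.Series:
    if isinstance(obj, StageAssignment):
        return pd.Series(obj.stages, index=obj.subject_ids)
    return pd.Series(obj)


def stability_transitions(baseline, followup,
                          n_stages: int | None = None) -> TransitionMatrix:
    """Cross-tabulate paired baseline and follow-up stage assignments."""
    b, f = _stage_series(baseline), _stage_series(followup)
    common = b.index.intersection(f.index)
    if len(common) == 0:
        raise ValueError("no paired subjects between baseline and follow-up")
    b, f = b.loc[common].to_numpy(int), f.loc[common].to_numpy(int)
    if n_stages is None:
        n_stages = int(max(b.max(), f.max())) + 1
    counts = np.zeros((n_stages, n_stages), int)
    np.add.at(counts, (b, f), 1)
    n = len(common)
    stable = float((f == b).sum()) / n * 100.0
    progressed = float((f > b).sum()) / n * 100.0
    regressed = float((f < b).sum()) / n * 100.0
    n_prog = (f > b).sum()
    one = float((f - b == 1).sum()) / n_prog * 100.0 if n_prog else np.nan
    return TransitionMatrix(counts, stable, progressed, regressed, one)


# ---------------------------------------------------------------------------
# stage-stratified survival
# ---------------------------------------------------------------------------

def stage_group_labels(stages) -> pd.Series:
    """Survival grouping: stage 0, positive-low (1-3), high (4-5+)."""
    s = np.asarray(stages, int)
    lab = np.where(s == 0, "0", np.where(s <= 3, "1-3", "4-5"))
    return pd.Series(lab)


@dataclass
class SurvivalResult:
    """KM curves per stage group plus a Cox hazard ratio for high vs low."""

    km_curves: dict[str, pd.DataFrame]
    median_times: dict[str, float]
    hazard_ratio: float
    hr_ci: tuple[float, float]
    p_value: float
    covariates: list[str] = field(default_factory=list)
    note: str = ""

    def __post_init__(self) -> None:
        for g, curve in self.km_curves.items():
            surv = curve["survival"].to_numpy()
            if np.any(np.diff(surv) > 1e-12):
                raise ValueError(f"KM curve for group {g!r} must be non-increasing")
        if np.isfinite(self.hazard_ratio) and self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be positive")


def km_cox(
    time,
    event,
    group,
    covariates: pd.DataFrame | None = None,
    reference: str = "1-3",
    comparison: str = "4-5",
) -> SurvivalResult:
    """Kaplan-Meier curves per group and a Cox HR (Efron ties) for
    ``comparison`` vs ``reference``, adjusted for ``covariates``.

    With zero events in either compared group the partial likelihood is
    monotone and the HR is reported as undefined (NaN) with a note.
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter

    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, object)
    if np.any(time[~np.isnan(time)] <= 0):
        raise ValueError("survival times must be positive")

    km_curves, medians = {}, {}
    for g in pd.unique(group):
        mask = group == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        ci = kmf.confidence_interval_survival_function_
        km_curves[str(g)] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "ci_lower": ci.iloc[:, 0].to_numpy(),
                "ci_upper": ci.iloc[:, 1].to_numpy(),
            }
        )
        medians[str(g)] = float(kmf.median_survival_time_)

    in_pair = np.isin(group, [reference, comparison])
    ref_events = int(event[(group == reference)].sum())
    cmp_events = int(event[(group == comparison)].sum())
    covnames = list(covariates.columns) if covariates is not None else []
    if ref_events == 0 or cmp_events == 0:
        note = (
            f"HR undefined: zero events in "
            f"{'reference' if ref_events == 0 else 'comparison'} group"
        )
        return SurvivalResult(km_curves, medians, np.nan, (np.nan, np.nan),
                              np.nan, covnames, note)

    df = pd.DataFrame(
        {
            "time": time[in_pair],
            "event": event[in_pair],
            "high": (group[in_pair] == comparison).astype(int),
        }
    )
    if covariates is not None:
        for c in covnames:
            df[c] = np.asarray(covariates[c])[in_pair]
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["high"]))
    lo, hi = cph.confidence_intervals_.loc["high"]
    p = float(cph.summary.loc["high", "p"])
    return SurvivalResult(
        km_curves, medians, hr, (float(np.exp(lo)), float(np.exp(hi))), p,
        covnames,
    )
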