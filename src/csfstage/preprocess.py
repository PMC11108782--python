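"""Reference z-scoring and two-component Gaussian abnormality mixtures.

Raw biomarker values are standardized against a biomarker-negative reference
group (cognitively unimpaired, amyloid-negative participants above a minimum
age), inverted where necessary so that higher z means more abnormal, and
then modeled per biomarker as a two-component Gaussian mixture.  The two
component densities evaluated at a subject's z-score are the inputs of the
event-based sequence likelihood.

Densities (not normalized posterior probabilities) are carried downstream:
the mixture weight would enter every stage term of the sequence likelihood
as the same per-subject constant and therefore cancels from all ordering
comparisons; carrying densities keeps the likelihood in the mixture
event-based form.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .panel import BiomarkerPanel

logger = logging.getLogger(__name__)

SD_FLOOR = 0.05
EM_TOL = 1e-6
EM_MAX_ITER = 500


class DegenerateComponentError(ValueError):
    """EM collapsed or the data carry no variance for a biomarker."""


class ConvergenceError(RuntimeError):
    """EM failed to converge within the iteration budget."""


# ---------------------------------------------------------------------------
# z-scoring
# ---------------------------------------------------------------------------

@dataclass
class ZScoreModel:
    """Per-biomarker reference mean/sd plus inversion flags.

    ``invert[name]`` is True for markers whose raw abnormality is a decrease;
    their z-scores are negated so that higher always means more abnormal.
    """

    means: dict[str, float]
    sds: dict[str, float]
    invert: dict[str, bool]
    reference_rule: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, sd in self.sds.items():
            if not sd > 0:
                raise ValueError(f"reference sd must be positive for {name!r}")

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "means": self.means,
                "sds": self.sds,
                "invert": self.invert,
                "reference_rule": self.reference_rule,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path) -> "ZScoreModel":
        try:
            d = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                d = json.load(fh)
        return cls(d["means"], d["sds"], d["invert"], d.get("reference_rule", {}))


def select_reference(
    cohort: pd.DataFrame,
    label: str = "CU-",
    min_age: float = 60.0,
) -> pd.Series:
    """Boolean mask of reference rows.

    Uses the explicit ``reference_flag`` column when present; otherwise the
    rule "diagnosis == label and age > min_age".
    """
    if "reference_flag" in cohort.columns:
        return cohort["reference_flag"].astype(bool)
    mask = (cohort["diagnosis"] == label) & (cohort["age"] > min_age)
    return mask


def fit_reference_zscore(
    cohort: pd.DataFrame,
    panel: BiomarkerPanel,
    label: str = "CU-",
    min_age: float = 60.0,
) -> ZScoreModel:
    """Fit reference means/sds on the biomarker-negative reference group."""
    mask = select_reference(cohort, label, min_age)
    ref = cohort.loc[mask]
    if ref.empty:
        raise ValueError(
            "empty reference group under rule "
            f"(reference_flag or diagnosis == {label!r} and age > {min_age})"
        )
    means, sds, invert = {}, {}, {}
    for name in panel.names:
        vals = ref[name].dropna().to_numpy(float)
        if len(vals) < 2:
            raise ValueError(
                f"need >= 2 non-missing reference values for {name!r}, got {len(vals)}"
            )
        means[name] = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        if not sd > 0:
            raise ValueError(f"zero reference variance for {name!r}")
        sds[name] = sd
        invert[name] = panel.directions[name] == "decrease"
    return ZScoreModel(means, sds, invert,
                       {"label": label, "min_age": min_age})


def apply_zscore(cohort: pd.DataFrame, model: ZScoreModel) -> pd.DataFrame:
    """Direction-signed z-matrix, indexed like ``cohort``.

    z = sign * (x - mean) / sd with sign -1 for inverted markers; missing
    values propagate as missing.
    """
    missing = [n for n in model.means if n not in cohort.columns]
    if missing:
        raise KeyError(f"cohort lacks biomarker columns: {missing}")
    out = {}
    for name, mean in model.means.items():
        z = (cohort[name].astype(float) - mean) / model.sds[name]
        out[name] = -z if model.invert[name] else z
    return pd.DataFrame(out, index=cohort.index)


def invert_zscore(z: pd.DataFrame, model: ZScoreModel) -> pd.DataFrame:
    """Inverse of :func:`apply_zscore` (z back to raw units)."""
    out = {}
    for name, mean in model.means.items():
        v = -z[name] if model.invert[name] else z[name]
        out[name] = v * model.sds[name] + mean
    return pd.DataFrame(out, index=z.index)


# ---------------------------------------------------------------------------
# two-component Gaussian mixtures
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    """One biomarker's two-Gaussian fit on the abnormality z scale.

    Components are canonically ordered with mu_abnormal >= mu_normal;
    ``weight`` is the abnormal-component mixing proportion.  ``loglik_trace``
    retains the per-iteration EM objective.
    """

    mu_normal: float
    sd_normal: float
    mu_abnormal: float
    sd_abnormal: float
    weight: float
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0

    def __post_init__(self) -> None:
        if not (self.sd_normal > 0 and self.sd_abnormal > 0):
            raise DegenerateComponentError("component sds must be positive")
        if self.mu_abnormal < self.mu_normal:
            raise ValueError("components must be ordered mu_abnormal >= mu_normal")
        if not 0.0 < self.weight < 1.0:
            raise ValueError("mixing weight must lie in (0, 1)")

    def density_normal(self, z):
        return norm.pdf(z, self.mu_normal, self.sd_normal)

    def density_abnormal(self, z):
        return norm.pdf(z, self.mu_abnormal, self.sd_abnormal)

    def prob_abnormal(self, z):
        """Posterior P(abnormal | z) under the fitted mixture."""
        pa = self.weight * self.density_abnormal(z)
        pn = (1.0 - self.weight) * self.density_normal(z)
        return pa / (pa + pn)


def _em_two_gaussians(
    z: np.ndarray,
    init: tuple[float, float, float, float, float],
    name: str,
    sd_floor: float = SD_FLOOR,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    fix_mu_normal: bool = False,
    fix_sd_normal: bool = False,
) -> MixtureFit:
    mu_n, sd_n, mu_a, sd_a, w = init
    sd_n, sd_a = max(sd_n, sd_floor), max(sd_a, sd_floor)
    trace: list[float] = []
    ll_old = -np.inf
    converged = False
    for it in range(max_iter):
        log_n = norm.logpdf(z, mu_n, sd_n) + np.log1p(-w)
        log_a = norm.logpdf(z, mu_a, sd_a) + np.log(w)
        log_tot = np.logaddexp(log_n, log_a)
        ll = float(log_tot.sum())
        trace.append(ll)
        # tolerance on the mean per-observation log-likelihood change
        if it > 0 and abs(ll - ll_old) < tol * len(z):
            converged = True
            break
        ll_old = ll
        r_a = np.exp(log_a - log_tot)
        r_n = 1.0 - r_a
        w = float(np.clip(r_a.mean(), 1e-6, 1 - 1e-6))
        for r, which in ((r_n, "n"), (r_a, "a")):
            tot = r.sum()
            if tot <= 0:
                raise DegenerateComponentError(
                    f"{name}: a mixture component lost all responsibility"
                )
            if which == "n":
                mu = mu_n if fix_mu_normal else float((r * z).sum() / tot)
            else:
                mu = float((r * z).sum() / tot)
            var = float((r * (z - mu) ** 2).sum() / tot)
            if var < 1e-12 and np.ptp(z) < 1e-12:
                raise DegenerateComponentError(f"{name}: zero-variance component")
            sd = max(np.sqrt(var), sd_floor)
            if which == "n":
                mu_n = mu
                if not fix_sd_normal:
                    sd_n = sd
            else:
                mu_a, sd_a = mu, sd
    if not converged:
        raise ConvergenceError(
            f"EM did not converge for biomarker {name!r} in {max_iter} iterations"
        )
    if mu_a < mu_n:  # canonical component order
        mu_n, sd_n, mu_a, sd_a, w = mu_a, sd_a, mu_n, sd_n, 1.0 - w
    return MixtureFit(mu_n, sd_n, mu_a, sd_a, w, trace, len(trace))


@dataclass
class MixtureModel:
    """Per-biomarker mixture fits, keyed by biomarker name."""

    fits: dict[str, MixtureFit]

    @property
    def biomarkers(self) -> list[str]:
        return list(self.fits)

    def __getitem__(self, name: str) -> MixtureFit:
        return self.fits[name]

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                name: {
                    "mu_normal": f.mu_normal,
                    "sd_normal": f.sd_normal,
                    "mu_abnormal": f.mu_abnormal,
                    "sd_abnormal": f.sd_abnormal,
                    "weight": f.weight,
                }
                for name, f in self.fits.items()
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path) -> "MixtureModel":
        try:
            d = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                d = json.load(fh)
        return cls({name: MixtureFit(**params) for name, params in d.items()})


def fit_event_mixtures(
    z: pd.DataFrame,
    reference_mask: np.ndarray | pd.Series | None = None,
    amyloid_status: np.ndarray | pd.Series | None = None,
    min_subjects: int = 20,
    init: tuple[float, float, float, float, float] | None = None,
    sd_floor: float = SD_FLOOR,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    anchor: str | None = "mean",
) -> MixtureModel:
    """Fit a two-Gaussian mixture per biomarker column of a z-matrix.

    When ``reference_mask`` marks a biomarker-negative reference group (the
    default pipeline), ``anchor`` controls how strongly the normal component
    is tied to that group: ``"mean"`` (default) pins the normal mean at the
    reference mean and lets EM re-estimate its sd — a free normal mean
    drifts off the reference anchor and misorders adjacent events, while a
    fully pinned sd inherits the reference subsample's sampling noise and
    lets the abnormal component absorb the normal bulk; ``"mean_sd"`` pins
    both; ``None`` runs a fully free two-component EM (also used when no
    mask is given), initialized from the lower half / upper tercile.  When
    ``amyloid_status`` is given, components are initialized from the
    amyloid-negative / amyloid-positive subgroups and fit freely; EM always
    runs on all subjects.
    """
    if anchor not in (None, "mean", "mean_sd"):
        raise ValueError("anchor must be None, 'mean' or 'mean_sd'")
    fits = {}
    for name in z.columns:
        vals = z[name].dropna().to_numpy(float)
        if len(vals) < min_subjects:
            raise ValueError(
                f"need >= {min_subjects} subjects to fit mixtures for {name!r}"
            )
        if np.ptp(vals) < 1e-12:
            raise DegenerateComponentError(f"{name}: all values identical")
        fix_mu = fix_sd = False
        if init is not None:
            start = init
        elif amyloid_status is not None:
            status = np.asarray(amyloid_status, bool)[z[name].notna().to_numpy()]
            neg, pos = vals[~status], vals[status]
            if len(neg) < 2 or len(pos) < 2:
                raise ValueError(f"{name}: need both amyloid groups for init")
            start = (
                float(neg.mean()), float(neg.std()),
                float(pos.mean()), float(pos.std()),
                float(status.mean()),
            )
        else:
            if reference_mask is not None:
                ref = np.asarray(reference_mask, bool)[z[name].notna().to_numpy()]
                if ref.sum() < 2:
                    raise ValueError(f"{name}: need >= 2 reference subjects")
                ref_vals = vals[ref]
                fix_mu = anchor in ("mean", "mean_sd")
                fix_sd = anchor == "mean_sd"
                ref_sd = float(np.std(ref_vals, ddof=1))
            else:
                ref_vals = vals[vals <= np.median(vals)]
                ref_sd = float(ref_vals.std())
            hi = vals[vals >= np.quantile(vals, 2.0 / 3.0)]
            start = (
                float(ref_vals.mean()), max(ref_sd, sd_floor),
                float(hi.mean()), float(max(hi.std(), sd_floor)),
                1.0 / 3.0,
            )
        fits[name] = _em_two_gaussians(
            vals, start, name, sd_floor=sd_floor, tol=tol, max_iter=max_iter,
            fix_mu_normal=fix_mu, fix_sd_normal=fix_sd,
        )
    return MixtureModel(fits)


def refine_event_mixtures(
    z: pd.DataFrame,
    abnormality_posterior: np.ndarray,
    reference_mask: np.ndarray | pd.Series | None = None,
    sd_floor: float = SD_FLOOR,
) -> MixtureModel:
    """One M-step of joint mixture/sequence estimation.

    Re-estimates each biomarker's two components from responsibility
    weights supplied by the sequence model's per-event abnormality
    posterior (which pools information across biomarkers through the
    subject's stage), instead of the marginal per-biomarker EM
    responsibilities.  Reference subjects are treated as labeled normal
    (responsibility clamped to the normal component).  Marginal
    two-Gaussian fits are weakly identified where the components overlap;
    a handful of these refinement rounds interleaved with sequence refits
    removes most of that estimation error.
    """
    a = np.asarray(abnormality_posterior, float)
    if a.shape != (len(z), len(z.columns)):
        raise ValueError("posterior shape does not match the z-matrix")
    a = np.clip(a, 0.0, 1.0).copy()
    if reference_mask is not None:
        a[np.asarray(reference_mask, bool)] = 0.0
    fits = {}
    for i, name in enumerate(z.columns):
        v = z[name].to_numpy(float)
        ok = np.isfinite(v)
        vi, ai = v[ok], a[ok, i]
        ni = 1.0 - ai
        if ai.sum() <= 0 or ni.sum() <= 0:
            raise DegenerateComponentError(
                f"{name}: a component lost all responsibility during refinement"
            )
        w = float(np.clip(ai.mean(), 1e-6, 1 - 1e-6))
        mu_n = float((ni * vi).sum() / ni.sum())
        sd_n = max(float(np.sqrt((ni * (vi - mu_n) ** 2).sum() / ni.sum())),
                   sd_floor)
        mu_a = float((ai * vi).sum() / ai.sum())
        sd_a = max(float(np.sqrt((ai * (vi - mu_a) ** 2).sum() / ai.sum())),
                   sd_floor)
        if mu_a < mu_n:
            mu_n, sd_n, mu_a, sd_a, w = mu_a, sd_a, mu_n, sd_n, 1.0 - w
        fits[name] = MixtureFit(mu_n, sd_n, mu_a, sd_a, w)
    return MixtureModel(fits)


# ---------------------------------------------------------------------------
# event probabilities
# ---------------------------------------------------------------------------

@dataclass
class EventProbabilityMatrix:
    """Per subject x biomarker component densities.

    ``p_normal[j, i]`` / ``p_abnormal[j, i]`` are the Gaussian densities of
    subject j's z-score for biomarker i under the normal / abnormal mixture
    component.  Rows are aligned to ``subject_ids``; subjects with any
    missing biomarker are excluded (complete-case policy) and counted in
    ``n_excluded``.
    """

    subject_ids: np.ndarray
    biomarkers: list[str]
    p_normal: np.ndarray
    p_abnormal: np.ndarray
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.p_normal = np.asarray(self.p_normal, float)
        self.p_abnormal = np.asarray(self.p_abnormal, float)
        for arr in (self.p_normal, self.p_abnormal):
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError("densities must be finite and non-negative")
        if self.p_normal.shape != self.p_abnormal.shape:
            raise ValueError("density matrices must share a shape")
        if self.p_normal.shape != (len(self.subject_ids), len(self.biomarkers)):
            raise ValueError("density matrix shape does not match labels")

    @property
    def n_subjects(self) -> int:
        return self.p_normal.shape[0]

    @property
    def n_events(self) -> int:
        return self.p_normal.shape[1]

    def subset(self, row_mask) -> "EventProbabilityMatrix":
        row_mask = np.asarray(row_mask)
        return EventProbabilityMatrix(
            self.subject_ids[row_mask],
            list(self.biomarkers),
            self.p_normal[row_mask],
            self.p_abnormal[row_mask],
        )


def event_probabilities(
    z: pd.DataFrame,
    mixtures: MixtureModel,
    subject_ids: np.ndarray | pd.Series | None = None,
) -> EventProbabilityMatrix:
    """Evaluate per-subject component densities under the fitted mixtures.

    Biomarker order follows the z-matrix columns."""
    missing = [n for n in z.columns if n not in mixtures.fits]
    if missing:
        raise KeyError(f"mixtures lack biomarkers: {missing}")
    cols = list(z.columns)
    zz = z[cols]
    complete = zz.notna().all(axis=1).to_numpy()
    n_excluded = int((~complete).sum())
    if n_excluded:
        logger.info("event_probabilities: excluded %d incomplete subjects",
                    n_excluded)
    zz = zz.loc[complete]
    if subject_ids is None:
        ids = zz.index.to_numpy()
    else:
        ids = np.asarray(subject_ids)[complete]
    zmat = zz.to_numpy(float)
    p_n = np.column_stack(
        [mixtures[c].density_normal(zmat[:, i]) for i, c in enumerate(cols)]
    )
    p_a = np.column_stack(
        [mixtures[c].density_abnormal(zmat[:, i]) for i, c in enumerate(cols)]
    )
    return EventProbabilityMatrix(ids, list(cols), p_n, p_a, n_excluded)
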