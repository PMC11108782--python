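"""Synthetic cohort generator.

Emulates the statistical structure the staging analysis assumes: a planted
event ordering per subtype, a stage distribution over 0..N, two-component
Gaussian observation noise per biomarker, stage-linked binary/ordinal
outcomes, longitudinal follow-up with mostly-forward stage transitions, and
censored progression times with stage-dependent hazards.  Every downstream
module is testable against the planted truth columns (``truth_stage``,
``truth_subtype``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .panel import BiomarkerPanel, default_panel

DIAGNOSIS_LEVELS = ("CU-", "CU+", "MCI+", "ADD+")

#: Baseline stage occupancy 0..5 used as the generator default
#: (fractions 29.1/8.2/12.4/11.5/20.4/18.3% of a 426-subject cohort).
DEFAULT_STAGE_COUNTS = (124, 35, 53, 49, 87, 78)


@dataclass
class OutcomeLinks:
    """Stage-linked outcome models.

    PET positivity is logistic in (stage - center) with the given steepness,
    placing the Youden-optimal stage cutoffs at 2 (amyloid) and 4 (tau) by
    construction.  The ordinal diagnosis arises from a noisy latent stage
    thresholded at ``diagnosis_cutpoints``.
    """

    amyloid_center: float = 1.5
    amyloid_steepness: float = 4.0
    tau_center: float = 3.5
    tau_steepness: float = 4.0
    diagnosis_cutpoints: tuple[float, ...] = (0.5, 2.5, 3.5)
    diagnosis_noise: float = 0.5
    centiloid_per_stage: float = 15.0
    centiloid_sd: float = 10.0
    suvr_intercept: float = 1.1
    suvr_per_stage: float = 0.12
    suvr_sd: float = 0.08
    composite_per_stage: float = -0.5
    composite_sd: float = 1.0


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    ``orderings`` holds one planted permutation of ``biomarker_names`` per
    subtype; ``subtype_fractions`` and ``stage_distribution`` must each sum
    to 1.  Biomarkers are emitted on a latent abnormality z scale (normal
    component N(0, 1), abnormal component N(effect_mean, effect_sd)) and
    then mapped to the raw scale as ``center + sign * scale * z`` where the
    sign is -1 for markers whose raw abnormality is a decrease.
    """

    n_subjects: int = 426
    panel: BiomarkerPanel = field(default_factory=default_panel)
    orderings: tuple[tuple[str, ...], ...] = ()
    subtype_fractions: tuple[float, ...] = (1.0,)
    stage_distribution: tuple[float, ...] = tuple(
        c / sum(DEFAULT_STAGE_COUNTS) for c in DEFAULT_STAGE_COUNTS
    )
    effect_mean: float | dict[str, float] = 3.0
    effect_sd: float | dict[str, float] = 1.5
    reference_fraction: float = 0.5
    outcome_links: OutcomeLinks = field(default_factory=OutcomeLinks)
    #: progression hazard per year for stage groups 0, 1-3 and 4-5
    hazard_per_stage_group: tuple[float, float, float] = (0.0, 0.02, 0.15)
    censoring_years: float = 5.0
    followup_years_mean: float = 2.05
    followup_years_sd: float = 0.22
    #: P(stay), P(advance one stage), P(regress one stage) between visits
    transition_probs: tuple[float, float, float] = (0.832, 0.139, 0.029)
    raw_scale: dict[str, tuple[float, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.orderings:
            self.orderings = (tuple(self.panel.names),)
        self.orderings = tuple(tuple(o) for o in self.orderings)
        for o in self.orderings:
            if sorted(o) != sorted(self.panel.names):
                raise ValueError(
                    f"ordering {o} is not a permutation of the panel biomarkers"
                )
        if len(self.orderings) != len(self.subtype_fractions):
            raise ValueError("one ordering required per subtype fraction")
        if abs(sum(self.subtype_fractions) - 1.0) > 1e-9:
            raise ValueError("subtype_fractions must sum to 1")
        if abs(sum(self.stage_distribution) - 1.0) > 1e-9:
            raise ValueError("stage_distribution must sum to 1")
        if len(self.stage_distribution) != len(self.panel) + 1:
            raise ValueError("stage_distribution must cover stages 0..N")
        if any(h < 0 for h in self.hazard_per_stage_group):
            raise ValueError("hazards must be non-negative")
        if abs(sum(self.transition_probs) - 1.0) > 1e-9:
            raise ValueError("transition_probs must sum to 1")

    # -- helpers -----------------------------------------------------------
    def _per_marker(self, value: float | dict[str, float]) -> np.ndarray:
        if isinstance(value, dict):
            return np.array([value[n] for n in self.panel.names], float)
        return np.full(len(self.panel), float(value))

    def effect_means(self) -> np.ndarray:
        return self._per_marker(self.effect_mean)

    def effect_sds(self) -> np.ndarray:
        return self._per_marker(self.effect_sd)

    def raw_params(self) -> tuple[np.ndarray, np.ndarray]:
        """(center, scale) arrays for the z -> raw affine map."""
        if self.raw_scale is None:
            centers = np.zeros(len(self.panel))
            scales = np.ones(len(self.panel))
        else:
            centers = np.array([self.raw_scale[n][0] for n in self.panel.names])
            scales = np.array([self.raw_scale[n][1] for n in self.panel.names])
        return centers, scales

    def hazard_of_stage(self, stage: int) -> float:
        if stage == 0:
            return self.hazard_per_stage_group[0]
        if stage <= 3:
            return self.hazard_per_stage_group[1]
        return self.hazard_per_stage_group[2]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["panel"] = self.panel.to_dict()
        d["orderings"] = [list(o) for o in self.orderings]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["panel"] = BiomarkerPanel.from_dict(d["panel"])
        d["orderings"] = tuple(tuple(o) for o in d["orderings"])
        if isinstance(d.get("outcome_links"), dict):
            d["outcome_links"] = OutcomeLinks(**d["outcome_links"])
        for key in ("subtype_fractions", "stage_distribution", "transition_probs",
                    "hazard_per_stage_group"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("raw_scale"):
            d["raw_scale"] = {k: tuple(v) for k, v in d["raw_scale"].items()}
        return cls(**d)


def _emit_biomarkers(
    stages: np.ndarray,
    subtypes: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Raw biomarker matrix (n x N) under the planted stage/subtype."""
    names = config.panel.names
    n, nbio = len(stages), len(names)
    mu_a, sd_a = config.effect_means(), config.effect_sds()
    # position of each biomarker in each subtype's ordering
    pos = np.array(
        [[config.orderings[c].index(names[i]) for i in range(nbio)]
         for c in range(len(config.orderings))]
    )
    abnormal = pos[subtypes] < stages[:, None]  # event occurred
    z = rng.standard_normal((n, nbio))
    z = np.where(abnormal, mu_a + sd_a * z, z)
    centers, scales = config.raw_params()
    signs = np.array([config.panel.sign(nm) for nm in names])
    return centers + signs * scales * z


def _draw_outcomes(
    stages: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    links = config.outcome_links
    n = len(stages)
    p_amy = expit(links.amyloid_steepness * (stages - links.amyloid_center))
    p_tau = expit(links.tau_steepness * (stages - links.tau_center))
    amyloid = rng.random(n) < p_amy
    tau = rng.random(n) < p_tau
    centiloids = links.centiloid_per_stage * stages + rng.normal(
        0.0, links.centiloid_sd, n
    )
    suvr = (
        links.suvr_intercept
        + links.suvr_per_stage * stages
        + rng.normal(0.0, links.suvr_sd, n)
    )
    composite = links.composite_per_stage * stages + rng.normal(
        0.0, links.composite_sd, n
    )
    latent = stages + rng.logistic(0.0, links.diagnosis_noise, n)
    diag_idx = np.searchsorted(np.asarray(links.diagnosis_cutpoints), latent)
    diagnosis = np.array(DIAGNOSIS_LEVELS, object)[diag_idx]
    return {
        "amyloid_pet_status": amyloid.astype(int),
        "centiloids": centiloids,
        "tau_pet_status": tau.astype(int),
        "tau_suvr": suvr,
        "cognitive_composite": composite,
        "diagnosis": diagnosis,
    }


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw a baseline cohort table with planted truth columns.

    One row per subject (``visit_time`` 0).  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    n_stages = len(config.stage_distribution)

    subtypes = rng.choice(len(config.subtype_fractions), n,
                          p=np.asarray(config.subtype_fractions))
    stages = rng.choice(n_stages, n, p=np.asarray(config.stage_distribution))
    values = _emit_biomarkers(stages, subtypes, config, rng)

    age = np.clip(rng.normal(71.5, 8.5, n) + 0.5 * stages, 45.0, 95.0)
    sex = rng.choice(["F", "M"], n)
    apoe4 = (rng.random(n) < np.clip(0.35 + 0.06 * stages, 0.0, 0.9)).astype(int)

    outcomes = _draw_outcomes(stages, config, rng)

    hazards = np.array([config.hazard_of_stage(int(s)) for s in stages])
    censor = rng.uniform(0.0, config.censoring_years, n)
    with np.errstate(divide="ignore"):
        event_time = np.where(
            hazards > 0, rng.exponential(1.0, n) / np.maximum(hazards, 1e-300),
            np.inf,
        )
    time_obs = np.minimum(event_time, censor)
    event = (event_time <= censor).astype(int)

    reference = np.zeros(n, bool)
    stage0 = np.flatnonzero(stages == 0)
    n_ref = int(round(config.reference_fraction * len(stage0)))
    if n_ref:
        reference[rng.choice(stage0, n_ref, replace=False)] = True

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "visit_time": 0.0,
        }
    )
    for j, name in enumerate(config.panel.names):
        df[name] = values[:, j]
    df["age"] = age
    df["sex"] = sex
    df["apoe4"] = apoe4
    for k, v in outcomes.items():
        df[k] = v
    df["time_to_event"] = time_obs
    df["event"] = event
    df["reference_flag"] = reference
    df["truth_stage"] = stages
    df["truth_subtype"] = subtypes
    return df


def simulate_followup(
    cohort: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Append a second visit per subject.

    The follow-up stage is drawn from ``config.transition_probs``
    (stay / advance one / regress one) and clipped to the valid stage range;
    biomarker values are re-emitted under the follow-up stage.  Returns the
    combined two-visit table.
    """
    if "truth_stage" not in cohort.columns:
        raise ValueError("baseline truth stages required to simulate follow-up")
    base = cohort[cohort["visit_time"] == cohort["visit_time"].min()]
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = len(base)
    n_stages = len(config.stage_distribution)

    moves = rng.choice([0, 1, -1], n, p=np.asarray(config.transition_probs))
    stages = np.clip(base["truth_stage"].to_numpy() + moves, 0, n_stages - 1)
    subtypes = base["truth_subtype"].to_numpy()
    values = _emit_biomarkers(stages, subtypes, config, rng)
    dt = np.maximum(
        rng.normal(config.followup_years_mean, config.followup_years_sd, n), 0.1
    )

    fu = base.copy()
    fu["visit_time"] = base["visit_time"].to_numpy() + dt
    for j, name in enumerate(config.panel.names):
        fu[name] = values[:, j]
    fu["age"] = base["age"].to_numpy() + dt
    out = _draw_outcomes(stages, config, rng)
    for k, v in out.items():
        fu[k] = v
    fu["truth_stage"] = stages
    return (
        pd.concat([base, fu], ignore_index=True)
        .sort_values(["subject_id", "visit_time"])
        .reset_index(drop=True)
    )


def shuffle_null(
    cohort: pd.DataFrame,
    seed: int,
    biomarkers: list[str] | tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Destroy cross-biomarker structure while preserving marginals.

    Each biomarker column is independently permuted across rows (a random
    shuffle without resampling).  A single-row cohort is returned unchanged.
    """
    out = cohort.copy()
    if len(out) < 2:
        return out
    if biomarkers is None:
        biomarkers = [n for n in default_panel().names if n in out.columns]
        if not biomarkers:
            raise ValueError("no biomarker columns found; pass them explicitly")
    rng = np.random.default_rng(seed)
    for name in biomarkers:
        out[name] = out[name].to_numpy()[rng.permutation(len(out))]
    return out


def simulate_longitudinal_outcome(
    cohort: pd.DataFrame,
    slopes_by_stage: dict[int, float],
    n_visits: int = 3,
    interval_years: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format repeated measurements with a planted per-stage slope.

    Used to exercise per-subject rate-of-change estimation: subject j at
    planted baseline stage k accrues value ``slope_k * t + noise``.
    """
    rng = np.random.default_rng(seed)
    base = cohort[cohort["visit_time"] == cohort["visit_time"].min()]
    rows = []
    for sid, stage in zip(base["subject_id"], base["truth_stage"]):
        slope = slopes_by_stage.get(int(stage), 0.0)
        for v in range(n_visits):
            t = v * interval_years
            rows.append(
                (sid, int(stage), t, slope * t + rng.normal(0.0, noise_sd))
            )
    return pd.DataFrame(rows, columns=["subject_id", "truth_stage", "time", "value"])
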