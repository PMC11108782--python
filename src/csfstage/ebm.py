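"""Event-based sequence model with subtype support.

The model assumes each biomarker switches once from a normal to an abnormal
regime, in an ordering S shared by all subjects of a subtype.  A subject at
stage k has the first k events of S in the abnormal regime.  With p_A and
p_N the abnormal/normal component densities of the observed values, the
stage-marginalized subject likelihood under a uniform stage prior is

    P(x | S) = 1/(N+1) * sum_{k=0..N} prod_{i<=k} p_A(x_{s(i)})
                                      * prod_{i>k} p_N(x_{s(i)})

and a C-subtype model mixes subtype-specific orderings S_c with fractions
f_c:  P(x) = sum_c f_c P(x | S_c).  Ordering inference combines multi-start
greedy pairwise-swap ascent with Metropolis-Hastings sampling over
permutations; subtypes are fit by hierarchical splitting followed by an
EM alternation of soft subject assignment and per-subtype ordering ascent.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, softmax

from .preprocess import EventProbabilityMatrix

_TIE_TOL = 1e-12


@dataclass
class SamplerSettings:
    """Knobs of the ordering sampler; all reducible for fast runs."""

    n_startpoints: int = 25
    mcmc_iters: int = 100_000
    thin: int = 10
    em_tol: float = 1e-6
    em_max_iter: int = 100
    n_split_trials: int = 5

    def to_dict(self) -> dict:
        return {
            "n_startpoints": self.n_startpoints,
            "mcmc_iters": self.mcmc_iters,
            "thin": self.thin,
            "em_tol": self.em_tol,
            "em_max_iter": self.em_max_iter,
            "n_split_trials": self.n_split_trials,
        }


@dataclass
class SequenceModel:
    """Fitted ordering(s), subtype fractions and retained posterior samples.

    ``orderings[c]`` lists biomarker indices in the order they become
    abnormal under subtype c.  ``mcmc_samples`` holds (orderings, loglik)
    pairs retained from the Metropolis-Hastings chain.
    """

    biomarkers: list[str]
    orderings: list[np.ndarray]
    fractions: np.ndarray
    log_likelihood: float
    seed: int | None = None
    settings: dict = field(default_factory=dict)
    mcmc_samples: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.biomarkers)
        self.orderings = [np.asarray(o, int) for o in self.orderings]
        for o in self.orderings:
            if sorted(o.tolist()) != list(range(n)):
                raise ValueError("each ordering must be a permutation of the events")
        self.fractions = np.asarray(self.fractions, float)
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("subtype fractions must sum to 1")
        if not np.isfinite(self.log_likelihood):
            warnings.warn("model log-likelihood is not finite", RuntimeWarning)

    @property
    def n_events(self) -> int:
        return len(self.biomarkers)

    @property
    def n_subtypes(self) -> int:
        return len(self.orderings)

    def ordering_names(self, subtype: int = 0) -> list[str]:
        return [self.biomarkers[i] for i in self.orderings[subtype]]

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "biomarkers": self.biomarkers,
                "orderings": [self.ordering_names(c) for c in range(self.n_subtypes)],
                "fractions": self.fractions.tolist(),
                "log_likelihood": self.log_likelihood,
                "seed": self.seed,
                "settings": self.settings,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path) -> "SequenceModel":
        try:
            d = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                d = json.load(fh)
        bio = d["biomarkers"]
        orderings = [np.array([bio.index(n) for n in o]) for o in d["orderings"]]
        return cls(bio, orderings, np.array(d["fractions"]),
                   d["log_likelihood"], d.get("seed"), d.get("settings", {}))


@dataclass
class PositionalConfusion:
    """P(event occupies sequence position), estimated over MCMC samples."""

    biomarkers: list[str]
    matrix: np.ndarray  # (event, position)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if not (
            np.allclose(m.sum(axis=0), 1.0, atol=1e-6)
            and np.allclose(m.sum(axis=1), 1.0, atol=1e-6)
        ):
            raise ValueError("confusion matrix must be doubly stochastic")
        self.matrix = m

    def to_tsv(self, path) -> None:
        import pandas as pd

        n = len(self.biomarkers)
        pd.DataFrame(
            self.matrix, index=self.biomarkers,
            columns=[f"position_{p + 1}" for p in range(n)],
        ).to_csv(path, sep="\t")


@dataclass
class StageAssignment:
    """Per-subject MAP stage plus stage and subtype posteriors."""

    subject_ids: np.ndarray
    stages: np.ndarray
    stage_posterior: np.ndarray  # (n, N+1)
    subtype_posterior: np.ndarray  # (n, C)

    def __post_init__(self) -> None:
        if not np.allclose(self.stage_posterior.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("stage posteriors must sum to 1")
        if not np.allclose(self.subtype_posterior.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("subtype posteriors must sum to 1")
        argmax = self.stage_posterior.argmax(axis=1)
        if not np.all(
            self.stage_posterior[np.arange(len(self.stages)), self.stages]
            >= self.stage_posterior[np.arange(len(self.stages)), argmax] - 1e-12
        ):
            raise ValueError("MAP stage must attain the maximal posterior mass")

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({"subject_id": self.subject_ids, "stage": self.stages})
        for k in range(self.stage_posterior.shape[1]):
            df[f"p_stage_{k}"] = self.stage_posterior[:, k]
        for c in range(self.subtype_posterior.shape[1]):
            df[f"p_subtype_{c}"] = self.subtype_posterior[:, c]
        return df


# ---------------------------------------------------------------------------
# likelihood kernels
# ---------------------------------------------------------------------------

def _safe_log(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(p)


def _stage_logterms(log_pn: np.ndarray, log_pa: np.ndarray,
                    ordering: np.ndarray) -> np.ndarray:
    """(n, N+1) matrix of log prod_{i<k} p_A * prod_{i>=k} p_N per stage k."""
    a = log_pa[:, ordering]
    b = log_pn[:, ordering]
    n = a.shape[0]
    zeros = np.zeros((n, 1))
    cum_a = np.concatenate([zeros, np.cumsum(a, axis=1)], axis=1)
    cum_b = np.concatenate(
        [np.cumsum(b[:, ::-1], axis=1)[:, ::-1], zeros], axis=1
    )
    return cum_a + cum_b


def _marginal_logliks(log_pn: np.ndarray, log_pa: np.ndarray,
                      ordering: np.ndarray) -> np.ndarray:
    """Per-subject log of the stage-marginalized likelihood (uniform prior)."""
    terms = _stage_logterms(log_pn, log_pa, ordering)
    n_stages = terms.shape[1]
    with np.errstate(invalid="ignore"):
        out = logsumexp(terms, axis=1) - np.log(n_stages)
    return np.where(np.all(np.isneginf(terms), axis=1), -np.inf, out)


def subject_loglik(p_normal, p_abnormal, ordering) -> float:
    """log P(x | S) for one subject, marginalized over stages 0..N."""
    p_n = np.atleast_2d(np.asarray(p_normal, float))
    p_a = np.atleast_2d(np.asarray(p_abnormal, float))
    if np.any(p_n < 0) or np.any(p_a < 0) or not (
        np.all(np.isfinite(p_n)) and np.all(np.isfinite(p_a))
    ):
        raise ValueError("densities must be finite and non-negative")
    ll = float(_marginal_logliks(_safe_log(p_n), _safe_log(p_a),
                                 np.asarray(ordering, int))[0])
    if np.isneginf(ll):
        warnings.warn("all stage terms are zero; subject likelihood is 0",
                      RuntimeWarning)
    return ll


def _mixture_logliks(log_pn, log_pa, orderings, fractions) -> np.ndarray:
    """Per-subject log sum_c f_c P(x | S_c)."""
    cols = [_marginal_logliks(log_pn, log_pa, o) for o in orderings]
    m = np.column_stack(cols)
    with np.errstate(divide="ignore", invalid="ignore"):
        return logsumexp(m + np.log(np.asarray(fractions)), axis=1)


def dataset_loglik(events: EventProbabilityMatrix, model: SequenceModel) -> float:
    """Total data log-likelihood sum_j log sum_c f_c P(x_j | S_c)."""
    if list(events.biomarkers) != list(model.biomarkers):
        raise ValueError(
            f"biomarker mismatch: events {events.biomarkers} vs model "
            f"{model.biomarkers}"
        )
    log_pn, log_pa = _safe_log(events.p_normal), _safe_log(events.p_abnormal)
    return float(
        _mixture_logliks(log_pn, log_pa, model.orderings, model.fractions).sum()
    )


def dataset_loglik_posterior(
    events: EventProbabilityMatrix, model: SequenceModel
) -> float:
    """Out-of-sample log-likelihood averaged over the ordering posterior.

    sum_j log (1/S) sum_s sum_c f_c P(x_j | S_c^(s)) over the retained MCMC
    samples.  Evaluating held-out data at a single point-estimate ordering
    denies a one-subtype model its ordering uncertainty while a multi-
    subtype mixture keeps averaging through its components, biasing
    cross-validated comparisons toward more subtypes; averaging over the
    posterior puts all subtype counts on the same footing.  Falls back to
    :func:`dataset_loglik` when no samples were retained.
    """
    if not model.mcmc_samples:
        return dataset_loglik(events, model)
    if list(events.biomarkers) != list(model.biomarkers):
        raise ValueError("biomarker mismatch between events and model")
    log_pn, log_pa = _safe_log(events.p_normal), _safe_log(events.p_abnormal)
    per_sample = np.column_stack(
        [
            _mixture_logliks(log_pn, log_pa, orderings, model.fractions)
            for orderings, _ in model.mcmc_samples
        ]
    )  # (n, S)
    with np.errstate(invalid="ignore"):
        avg = logsumexp(per_sample, axis=1) - np.log(per_sample.shape[1])
    return float(avg.sum())


# ---------------------------------------------------------------------------
# ordering optimization
# ---------------------------------------------------------------------------

def _is_better(ll: float, order: np.ndarray, best_ll: float,
               best_order: np.ndarray | None) -> bool:
    """Strictly higher likelihood wins; exact ties go to the
    lexicographically smaller ordering."""
    if best_order is None or ll > best_ll + _TIE_TOL:
        return True
    if ll >= best_ll - _TIE_TOL and tuple(order) < tuple(best_order):
        return True
    return False


def _greedy_ascent(log_pn, log_pa, order, weights=None):
    """Steepest-ascent pairwise-swap hill climbing on the (weighted)
    dataset log-likelihood; returns (ordering, score)."""

    def score(o):
        m = _marginal_logliks(log_pn, log_pa, o)
        return float(m.sum() if weights is None else (weights * m).sum())

    order = np.asarray(order, int).copy()
    n = len(order)
    current = score(order)
    pairs = list(itertools.combinations(range(n), 2))
    improved = True
    while improved:
        improved = False
        best_swap, best_score = None, current
        for i, j in pairs:
            order[i], order[j] = order[j], order[i]
            s = score(order)
            order[i], order[j] = order[j], order[i]
            if s > best_score + _TIE_TOL:
                best_swap, best_score = (i, j), s
        if best_swap is not None:
            i, j = best_swap
            order[i], order[j] = order[j], order[i]
            current = best_score
            improved = True
    return order, current


def _total_loglik(log_pn, log_pa, orderings, fractions) -> float:
    return float(_mixture_logliks(log_pn, log_pa, orderings, fractions).sum())


def _mcmc(log_pn, log_pa, orderings, fractions, settings: SamplerSettings,
          rng: np.random.Generator):
    """Metropolis-Hastings over orderings (symmetric two-position swap
    proposal within a random subtype); fractions are held fixed.

    Returns (samples, best_orderings, best_ll) where samples are thinned
    (orderings, loglik) states."""
    orderings = [o.copy() for o in orderings]
    n_sub = len(orderings)
    n_events = len(orderings[0])
    current = _total_loglik(log_pn, log_pa, orderings, fractions)
    best = [o.copy() for o in orderings]
    best_ll = current
    samples = []
    for it in range(settings.mcmc_iters):
        c = int(rng.integers(n_sub)) if n_sub > 1 else 0
        i, j = rng.choice(n_events, size=2, replace=False)
        orderings[c][i], orderings[c][j] = orderings[c][j], orderings[c][i]
        proposal = _total_loglik(log_pn, log_pa, orderings, fractions)
        if np.log(rng.random()) < proposal - current:
            current = proposal
            if proposal > best_ll + _TIE_TOL or (
                proposal >= best_ll - _TIE_TOL
                and [tuple(o) for o in orderings] < [tuple(o) for o in best]
            ):
                best = [o.copy() for o in orderings]
                best_ll = proposal
        else:
            orderings[c][i], orderings[c][j] = orderings[c][j], orderings[c][i]
        if (it + 1) % settings.thin == 0:
            samples.append(([o.copy() for o in orderings], current))
    return samples, best, best_ll


def _em_subtypes(log_pn, log_pa, orderings, fractions,
                 settings: SamplerSettings):
    """Alternate soft subject-to-subtype assignment with per-subtype
    weighted ordering ascent until the log-likelihood stabilizes."""
    orderings = [o.copy() for o in orderings]
    fractions = np.asarray(fractions, float).copy()
    prev = -np.inf
    for _ in range(settings.em_max_iter):
        m = np.column_stack(
            [_marginal_logliks(log_pn, log_pa, o) for o in orderings]
        )
        with np.errstate(divide="ignore"):
            joint = m + np.log(fractions)
        ll = float(logsumexp(joint, axis=1).sum())
        if abs(ll - prev) < settings.em_tol:
            break
        prev = ll
        resp = softmax(joint, axis=1)
        fractions = np.clip(resp.mean(axis=0), 1e-6, None)
        fractions /= fractions.sum()
        for c in range(len(orderings)):
            orderings[c], _ = _greedy_ascent(
                log_pn, log_pa, orderings[c], weights=resp[:, c]
            )
    ll = _total_loglik(log_pn, log_pa, orderings, fractions)
    return orderings, fractions, ll


def _fit_one_subtype(log_pn, log_pa, settings, rng):
    n_events = log_pn.shape[1]
    best_order, best_ll = None, -np.inf
    for _ in range(settings.n_startpoints):
        order, ll = _greedy_ascent(log_pn, log_pa, rng.permutation(n_events))
        if _is_better(ll, order, best_ll, best_order):
            best_order, best_ll = order, ll
    return [best_order], np.array([1.0]), best_ll


def fit_sequences(
    events: EventProbabilityMatrix,
    n_subtypes: int = 1,
    settings: SamplerSettings | None = None,
    seed: int | None = None,
) -> SequenceModel:
    """Infer subtype orderings and fractions; deterministic given ``seed``.

    One subtype: multi-start greedy ascent then Metropolis-Hastings over
    orderings.  More subtypes: hierarchical initialization splitting a
    cluster of the (C-1)-subtype model, then EM alternation of soft
    assignment and weighted ordering ascent, then joint MCMC.
    """
    if settings is None:
        settings = SamplerSettings()
    if seed is None:
        raise ValueError("a seed is required for reproducible fits")
    if n_subtypes < 1:
        raise ValueError("n_subtypes must be >= 1")
    if n_subtypes > events.n_subjects:
        raise ValueError("cannot fit more subtypes than subjects")
    rng = np.random.default_rng(seed)
    log_pn, log_pa = _safe_log(events.p_normal), _safe_log(events.p_abnormal)

    orderings, fractions, ll = _fit_one_subtype(log_pn, log_pa, settings, rng)
    for c in range(2, n_subtypes + 1):
        orderings, fractions, ll = _split_and_refit(
            log_pn, log_pa, orderings, fractions, settings, rng
        )

    samples, best, best_ll = _mcmc(
        log_pn, log_pa, orderings, fractions, settings, rng
    )
    if best_ll > ll + _TIE_TOL:
        orderings, ll = best, best_ll
    return SequenceModel(
        list(events.biomarkers),
        orderings,
        fractions,
        ll,
        seed=seed,
        settings=settings.to_dict(),
        mcmc_samples=samples,
    )


def _split_and_refit(log_pn, log_pa, orderings, fractions, settings, rng):
    """Grow a (C-1)-subtype solution to C subtypes by cluster splitting."""
    m = np.column_stack([_marginal_logliks(log_pn, log_pa, o) for o in orderings])
    with np.errstate(divide="ignore"):
        assign = np.argmax(m + np.log(fractions), axis=1)
    best = None
    n_trials = max(1, settings.n_split_trials)
    for trial in range(n_trials):
        # cycle through clusters large enough to split; fall back to largest
        sizes = np.array([(assign == c).sum() for c in range(len(orderings))])
        candidates = np.flatnonzero(sizes >= 4)
        if len(candidates) == 0:
            candidates = np.array([sizes.argmax()])
        target = int(candidates[trial % len(candidates)])
        members = np.flatnonzero(assign == target)
        if len(members) < 2:
            members = np.arange(log_pn.shape[0])
        half = rng.permutation(members)
        halves = (half[: len(half) // 2], half[len(half) // 2:])
        new_orders, new_fracs = [], []
        for c, o in enumerate(orderings):
            if c == target:
                for h in halves:
                    w = np.zeros(log_pn.shape[0])
                    w[h] = 1.0
                    o_h, _ = _greedy_ascent(log_pn, log_pa, o, weights=w)
                    new_orders.append(o_h)
                    new_fracs.append(fractions[c] * len(h) / max(len(members), 1))
            else:
                new_orders.append(o.copy())
                new_fracs.append(fractions[c])
        new_fracs = np.clip(np.asarray(new_fracs), 1e-6, None)
        new_fracs /= new_fracs.sum()
        fitted = _em_subtypes(log_pn, log_pa, new_orders, new_fracs, settings)
        if best is None or fitted[2] > best[2]:
            best = fitted
    return best


def event_abnormality_posterior(
    events: EventProbabilityMatrix, model: SequenceModel
) -> np.ndarray:
    """P(biomarker i abnormal | x_j, model) for every subject and event.

    Marginalizes the joint (subtype, stage) posterior: an event is abnormal
    when the subject's stage exceeds its position in the subject's subtype
    ordering.  Used to re-estimate mixture components jointly with the
    sequence model."""
    if list(events.biomarkers) != list(model.biomarkers):
        raise ValueError("events and model cover different biomarkers")
    log_pn, log_pa = _safe_log(events.p_normal), _safe_log(events.p_abnormal)
    n, n_events = events.n_subjects, events.n_events
    joint = np.stack(
        [_stage_logterms(log_pn, log_pa, o) for o in model.orderings], axis=1
    )
    with np.errstate(divide="ignore"):
        joint = joint + np.log(model.fractions)[None, :, None]
    flat = joint.reshape(n, -1)
    flat[np.all(np.isneginf(flat), axis=1)] = 0.0
    post = softmax(flat, axis=1).reshape(n, model.n_subtypes, n_events + 1)
    a = np.zeros((n, n_events))
    for c, o in enumerate(model.orderings):
        pos = np.empty(n_events, int)
        pos[o] = np.arange(n_events)
        for i in range(n_events):
            a[:, i] += post[:, c, pos[i] + 1:].sum(axis=1)
    return np.clip(a, 0.0, 1.0)


def refit_sequences(
    events: EventProbabilityMatrix,
    model: SequenceModel,
    settings: SamplerSettings | None = None,
    seed: int | None = None,
    sample: bool = True,
) -> SequenceModel:
    """Continue fitting from a previous solution (warm start).

    Re-optimizes orderings (and, with several subtypes, fractions) starting
    from ``model``, optionally followed by an MCMC pass to refresh the
    retained samples.  Used between mixture-refinement rounds so structure
    found earlier is tracked rather than rediscovered."""
    if settings is None:
        settings = SamplerSettings()
    if seed is None:
        raise ValueError("a seed is required")
    log_pn, log_pa = _safe_log(events.p_normal), _safe_log(events.p_abnormal)
    if model.n_subtypes == 1:
        order, ll = _greedy_ascent(log_pn, log_pa, model.orderings[0])
        orderings, fractions = [order], np.array([1.0])
    else:
        orderings, fractions, ll = _em_subtypes(
            log_pn, log_pa, model.orderings, model.fractions, settings
        )
    samples = []
    if sample and settings.mcmc_iters > 0:
        rng = np.random.default_rng(seed)
        samples, best, best_ll = _mcmc(
            log_pn, log_pa, orderings, fractions, settings, rng
        )
        if best_ll > ll + _TIE_TOL:
            orderings, ll = best, best_ll
    return SequenceModel(
        list(events.biomarkers), orderings, fractions, ll, seed=seed,
        settings=settings.to_dict(), mcmc_samples=samples,
    )


def brute_force_ml_ordering(
    events: EventProbabilityMatrix, max_events: int = 8
) -> tuple[np.ndarray, float]:
    """Exact single-subtype argmax over all N! orderings (test oracle).

    Ties resolve to the lexicographically smallest ordering.  Refuses
    N > ``max_events``.
    """
    n = events.n_events
    if n > max_events:
        raise ValueError(f"brute force refuses N={n} > {max_events} events")
    log_pn, log_pa = _safe_log(events.p_normal), _safe_log(events.p_abnormal)
    best_order, best_ll = None, -np.inf
    for perm in itertools.permutations(range(n)):
        order = np.array(perm)
        ll = float(_marginal_logliks(log_pn, log_pa, order).sum())
        if best_order is None or ll > best_ll + _TIE_TOL:
            best_order, best_ll = order, ll
    return best_order, best_ll


def positional_confusion(
    model: SequenceModel, subtype: int | None = None
) -> PositionalConfusion:
    """Event-at-position frequencies over the retained MCMC samples.

    With several subtypes and ``subtype=None`` the per-subtype matrices are
    averaged with the fitted fractions (still doubly stochastic)."""
    if not model.mcmc_samples:
        raise ValueError("no MCMC samples retained; refit with mcmc_iters > 0")
    n = model.n_events
    mats = np.zeros((model.n_subtypes, n, n))
    for orderings, _ in model.mcmc_samples:
        for c, o in enumerate(orderings):
            mats[c, o, np.arange(n)] += 1.0
    mats /= len(model.mcmc_samples)
    if subtype is not None:
        return PositionalConfusion(list(model.biomarkers), mats[subtype])
    combined = np.tensordot(model.fractions, mats, axes=1)
    return PositionalConfusion(list(model.biomarkers), combined)


def stage_subjects(
    events: EventProbabilityMatrix, model: SequenceModel
) -> StageAssignment:
    """MAP stage and stage/subtype posteriors for every subject.

    Posterior over (subtype, stage) is proportional to f_c P(x | S_c, k)
    under a uniform stage prior; equal-posterior stages resolve to the
    lower stage."""
    if list(events.biomarkers) != list(model.biomarkers):
        raise ValueError("events and model cover different biomarkers")
    log_pn, log_pa = _safe_log(events.p_normal), _safe_log(events.p_abnormal)
    n, n_stages = events.n_subjects, events.n_events + 1
    joint = np.stack(
        [_stage_logterms(log_pn, log_pa, o) for o in model.orderings], axis=1
    )  # (n, C, N+1)
    with np.errstate(divide="ignore"):
        joint = joint + np.log(model.fractions)[None, :, None]
    flat = joint.reshape(n, -1)
    dead = np.all(np.isneginf(flat), axis=1)
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} subject(s) have zero likelihood at every "
            "stage; assigning a uniform posterior", RuntimeWarning,
        )
        flat[dead] = 0.0
    post = softmax(flat, axis=1).reshape(n, model.n_subtypes, n_stages)
    stage_post = post.sum(axis=1)
    subtype_post = post.sum(axis=2)
    map_stage = np.argmax(stage_post, axis=1)  # argmax takes the first
    # guard against float noise pushing MAP above an equal lower stage
    for j in range(n):
        ties = np.flatnonzero(
            stage_post[j] >= stage_post[j, map_stage[j]] - _TIE_TOL
        )
        map_stage[j] = ties[0]
    return StageAssignment(events.subject_ids, map_stage, stage_post,
                           subtype_post)
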