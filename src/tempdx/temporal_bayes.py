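"""Bayesian temporal pattern matching over a disease-finding knowledge base.

The engine ranks diseases for a patient by naive-Bayes pattern matching:
an age- and gender-dependent incidence prior is multiplied by one
likelihood factor per observation, where each factor follows the
temporal model of the finding in the disease — its overall frequency,
a linear onset ramp across the curated onset-age interval and, when
curated, a linear disappearance ramp.  Observed onset ages are matched
against the onset model; findings explicitly recorded as absent act as
pertinent negatives (their likelihood is the complement of the expected
presence probability at the patient's age); findings a disease has no
curated association for fall back to a small background frequency so
that sparse curation never zeroes a disease out.  An optional observed
acuity of onset (the minutes-to-years timescale over which the illness
emerged) is matched against each disease's acuity class on a log-time
scale.

All products are accumulated in log space and normalized into a
:class:`Differential` — the ranked list of posterior probabilities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .knowledge_base import (
    ACUITY_SCALE,
    MAX_AGE,
    Disease,
    DiseaseFinding,
    KnowledgeBase,
)

GENDERS = ("male", "female", "unspecified")


@dataclass(frozen=True)
class EngineParams:
    """Tunable constants of the matching engine.

    eps_floor
        Lower bound applied to every likelihood factor.  Keeps a single
        contradicted or mis-entered observation (the dominant failure
        mode of real users) from driving a disease's posterior to zero.
    f0
        Background probability that an uncurated finding is present in a
        disease.  Curation is sparse; absence of an association means
        "not curated", not "never occurs".
    bin_width
        Width in years of the window used to score an observed onset age
        against the onset ramp, so onset likelihoods stay probabilities.
    acuity_match / acuity_near / acuity_far
        Likelihood of the observed acuity class when the disease's class
        is identical / adjacent on the log-time scale / further away.
        Diseases with unknown acuity receive the neutral factor 1.
    """

    eps_floor: float = 1e-4
    f0: float = 0.005
    bin_width: float = 0.25
    acuity_match: float = 1.0
    acuity_near: float = 0.5
    acuity_far: float = 0.1


DEFAULT_PARAMS = EngineParams()


@dataclass(frozen=True)
class Observation:
    """A finding recorded for the patient, present or absent.

    ``onset_age`` (years) may accompany a present finding; ``value_note``
    is free text carried for display and ignored by the computation.
    """

    finding_id: str
    state: str  # "present" | "absent"
    onset_age: Optional[float] = None
    value_note: Optional[str] = None

    def __post_init__(self):
        if self.state not in ("present", "absent"):
            raise ValueError(f"observation state must be present/absent, got {self.state!r}")
        if self.onset_age is not None:
            if self.state != "present":
                raise ValueError("onset_age only allowed for present findings")
            if self.onset_age < 0:
                raise ValueError("onset_age must be >= 0")


@dataclass(frozen=True)
class PatientProfile:
    age: float
    gender: str = "unspecified"
    observations: tuple[Observation, ...] = ()
    acuity_observed: Optional[str] = None

    def __post_init__(self):
        if not (0.0 <= self.age <= MAX_AGE):
            raise ValueError(f"patient age {self.age} outside [0,{MAX_AGE:g}]")
        if self.gender not in GENDERS:
            raise ValueError(f"unknown gender {self.gender!r}")
        ids = [o.finding_id for o in self.observations]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate finding_ids among observations")
        for o in self.observations:
            if o.onset_age is not None and o.onset_age > self.age:
                raise ValueError(
                    f"onset_age {o.onset_age} of {o.finding_id} exceeds patient age {self.age}"
                )

    def observed_ids(self) -> set[str]:
        return {o.finding_id for o in self.observations}


@dataclass(frozen=True)
class Differential:
    """Ranked posterior over diseases; probabilities sum to 1."""

    entries: tuple[tuple[str, float], ...]
    log_evidence: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.entries)

    def rank_of(self, disease_id: str) -> int:
        """1-based rank of a disease in the differential."""
        for i, (did, _) in enumerate(self.entries, start=1):
            if did == disease_id:
                return i
        raise KeyError(disease_id)

    def top(self, n: int) -> list[tuple[str, float]]:
        return list(self.entries[:n])


def patient_from_json(doc: dict) -> PatientProfile:
    obs = tuple(
        Observation(
            finding_id=o["finding_id"],
            state=o.get("state", "present"),
            onset_age=o.get("onset_age"),
            value_note=o.get("value_note"),
        )
        for o in doc.get("observations", [])
    )
    return PatientProfile(
        age=float(doc["age"]),
        gender=doc.get("gender", "unspecified"),
        observations=obs,
        acuity_observed=doc.get("acuity"),
    )


def load_patient(path) -> PatientProfile:
    with open(path, "r", encoding="utf-8") as fh:
        return patient_from_json(json.load(fh))


# ---------------------------------------------------------------------------
# Priors and temporal likelihood primitives
# ---------------------------------------------------------------------------


def prior_weight(disease: Disease, age: float, gender: str = "unspecified") -> float:
    """Unnormalized prior: incidence weight of the age bin times the
    gender multiplier (unspecified gender averages the multipliers)."""
    prof = disease.incidence
    weight = None
    for (lo, hi), w in zip(prof.age_bins, prof.incidence_per_bin):
        if lo <= age < hi or (age == hi == MAX_AGE):
            weight = w
            break
    if weight is None:
        raise ValueError(f"age not covered: {age} outside bins of {disease.disease_id}")
    mults = prof.gender_multiplier
    if gender == "unspecified" or gender not in mults:
        mult = sum(mults.values()) / len(mults) if mults else 1.0
    else:
        mult = mults[gender]
    return weight * mult


def ramp_cdf(age: float, lo: float, hi: float) -> float:
    """Linear CDF ramping 0 to 1 across [lo, hi]; a step when lo == hi."""
    if age < lo:
        return 0.0
    if age >= hi:
        return 1.0
    return (age - lo) / (hi - lo)


def prob_present_at_age(assoc: DiseaseFinding, age: float) -> float:
    """Probability the finding is currently present at ``age``:
    frequency x P(onset <= age) x (1 - P(disappeared <= age))."""
    p = assoc.frequency * ramp_cdf(age, *assoc.onset)
    if assoc.disappearance is not None:
        p *= 1.0 - ramp_cdf(age, *assoc.disappearance)
    return p


def onset_bin_mass(assoc: DiseaseFinding, onset_age: float, bin_width: float) -> float:
    """Mass of the onset ramp inside the window of ``bin_width`` years
    centred on ``onset_age``.  A point onset interval contributes all of
    its mass if the point lies in the window."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = assoc.onset
    a, b = onset_age - bin_width / 2.0, onset_age + bin_width / 2.0
    if lo == hi:
        return 1.0 if a <= lo <= b else 0.0
    return ramp_cdf(b, lo, hi) - ramp_cdf(a, lo, hi)


def observation_likelihood(
    kb: KnowledgeBase,
    disease_id: str,
    obs: Observation,
    age: float,
    params: EngineParams = DEFAULT_PARAMS,
) -> float:
    """Likelihood of one observation under one disease, floored at
    ``params.eps_floor``.

    Curated associations use the temporal model; uncurated pairs fall
    back to the background frequency ``f0`` with onset treated as
    uniform over the patient's life so far.
    """
    if obs.finding_id not in kb.findings:
        raise KeyError(f"unknown finding_id {obs.finding_id!r}")
    assoc = kb.get_association(disease_id, obs.finding_id)
    if assoc is not None:
        if obs.state == "present":
            if obs.onset_age is None:
                lik = prob_present_at_age(assoc, age)
            else:
                lik = assoc.frequency * onset_bin_mass(assoc, obs.onset_age, params.bin_width)
                if assoc.disappearance is not None:
                    lik *= 1.0 - ramp_cdf(age, *assoc.disappearance)
        else:
            lik = 1.0 - prob_present_at_age(assoc, age)
    else:
        if obs.state == "present":
            if obs.onset_age is None:
                lik = params.f0
            elif age <= 0:
                lik = params.f0
            else:
                lik = min(params.f0 * params.bin_width / age, params.f0)
        else:
            lik = 1.0 - params.f0
    return max(lik, params.eps_floor)


def acuity_likelihood(
    disease: Disease, observed: str, params: EngineParams = DEFAULT_PARAMS
) -> float:
    """Match observed acuity of onset against the disease's class on the
    log-time scale; diseases without curated acuity are neutral."""
    if disease.acuity_class == "unknown" or disease.acuity_class not in ACUITY_SCALE:
        return 1.0
    if observed not in ACUITY_SCALE:
        return 1.0
    gap = abs(ACUITY_SCALE[disease.acuity_class] - ACUITY_SCALE[observed])
    if gap == 0:
        return params.acuity_match
    if gap == 1:
        return params.acuity_near
    return params.acuity_far


# ---------------------------------------------------------------------------
# Posterior
# ---------------------------------------------------------------------------


def posterior(
    kb: KnowledgeBase,
    patient: PatientProfile,
    params: EngineParams = DEFAULT_PARAMS,
) -> Differential:
    """Normalized posterior over all diseases in the KB.

    posterior(d) is proportional to prior_weight(d) times the product of
    observation likelihoods (and the acuity factor, if an acuity was
    observed).  Accumulation is in log space; observations are processed
    in a canonical order so the result is invariant to their input
    order.  Ties are broken lexicographically by disease id.
    """
    obs_sorted = sorted(patient.observations, key=lambda o: o.finding_id)
    log_scores: dict[str, float] = {}
    for did, disease in kb.diseases.items():
        prior = prior_weight(disease, patient.age, patient.gender)
        if prior <= 0.0:
            continue
        logp = math.log(prior)
        for obs in obs_sorted:
            logp += math.log(
                observation_likelihood(kb, did, obs, patient.age, params)
            )
        if patient.acuity_observed is not None:
            logp += math.log(acuity_likelihood(disease, patient.acuity_observed, params))
        log_scores[did] = logp
    if not log_scores:
        raise ValueError("no admissible disease: all priors are zero")
    m = max(log_scores.values())
    unnorm = {did: math.exp(lp - m) for did, lp in log_scores.items()}
    z = sum(unnorm.values())
    if z <= 0.0:
        raise ValueError("no admissible disease: posterior mass underflowed")
    entries = [(did, w / z) for did, w in unnorm.items()]
    for did in kb.diseases:
        if did not in log_scores:
            entries.append((did, 0.0))
    entries.sort(key=lambda e: (-e[1], e[0]))
    return Differential(entries=tuple(entries), log_evidence=m + math.log(z))


def update_with_observation(
    kb: KnowledgeBase,
    patient: PatientProfile,
    diff: Differential,
    obs: Observation,
    params: EngineParams = DEFAULT_PARAMS,
) -> Differential:
    """One-step Bayes update of an existing differential with a new
    observation (used by the suggestion module's lookahead)."""
    unnorm = []
    for did, p in diff.entries:
        if p == 0.0:
            unnorm.append((did, 0.0))
            continue
        unnorm.append(
            (did, p * observation_likelihood(kb, did, obs, patient.age, params))
        )
    z = sum(w for _, w in unnorm)
    if z <= 0.0:
        raise ValueError("no admissible disease after update")
    entries = sorted(((did, w / z) for did, w in unnorm), key=lambda e: (-e[1], e[0]))
    return Differential(entries=tuple(entries), log_evidence=diff.log_evidence + math.log(z))


def expand_categories(kb: KnowledgeBase, diff: Differential) -> list[tuple[str, float]]:
    """Aggregate posterior mass by disease category.

    A disease belonging to several categories contributes its full
    posterior to each, so category masses can exceed 1 in total.
    """
    mass: dict[str, float] = {}
    for did, p in diff.entries:
        disease = kb.diseases.get(did)
        if disease is None:
            continue
        for cid in disease.category_ids:
            mass[cid] = mass.get(cid, 0.0) + p
    return sorted(mass.items(), key=lambda e: (-e[1], e[0]))


def with_observation(patient: PatientProfile, obs: Observation) -> PatientProfile:
    """Return a copy of the profile with one more observation."""
    return replace(patient, observations=patient.observations + (obs,))
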