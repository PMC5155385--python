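"""Synthetic knowledge bases and simulated patients.

Real curated diagnostic databases are proprietary, so every other part
of the package is exercised against synthetic ones.  The generator
emulates the scale statistics of a mature multi-specialty database —
thousands of diseases averaging 22 curated findings each — with
mid-heavy Beta-distributed finding frequencies (curators mostly record
"often"/"sometimes" grades), log-normal disease incidence (a few common
diseases, a long rare tail) and piecewise-constant age profiles.

``simulate_patient`` is the generative mirror of the matching engine:
it draws a patient age from the disease's incidence profile, samples
each curated finding's presence from its frequency and its onset age
from the onset ramp, and adds a handful of curated-but-absent findings
as pertinent negatives.  ``corrupt_profile`` reproduces the input-error
modes seen when clinicians enter cases by hand: onset ages dropped,
findings omitted, findings misinterpreted (present/absent flipped) and
spurious findings entered that the case never contained.

Every operation takes an explicit seed and uses its own generator
stream, so identical seeds give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .knowledge_base import (
    ACUITY_CLASSES,
    MAX_AGE,
    Disease,
    DiseaseFinding,
    FindingDef,
    IncidenceProfile,
    KnowledgeBase,
)
from .temporal_bayes import Observation, PatientProfile


@dataclass(frozen=True)
class NoiseConfig:
    """Per-observation probabilities of the four user-input error modes."""

    p_drop_onset: float = 0.0
    p_omit_finding: float = 0.0
    p_misinterpret: float = 0.0
    p_spurious: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    """Knowledge-base and patient simulation settings.

    Defaults emulate the published scale of the database the engine
    models: 5405 diseases averaging 22 findings each.  The finding
    vocabulary size, onset-interval widths and incidence dispersion are
    unreported for the real database; the defaults here are plausible
    placeholders, not measurements.
    """

    seed: int = 0
    n_diseases: int = 5405
    n_findings: int = 800
    findings_per_disease_mean: float = 22.0
    frequency_beta: tuple[float, float] = (2.0, 2.0)
    onset_span_years: tuple[float, float] = (0.0, 10.0)
    p_disappearance: float = 0.3
    incidence_lognormal: tuple[float, float] = (0.0, 1.0)
    p_core: float = 0.06
    n_categories: int = 20
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def __post_init__(self):
        if self.n_diseases < 1 or self.n_findings < 1:
            raise ValueError("counts must be >= 1")
        if self.n_findings < self.findings_per_disease_mean:
            raise ValueError(
                "n_findings must be at least findings_per_disease_mean"
            )


def _round6(x: float) -> float:
    # canonical 6-decimal values keep serialized KBs byte-identical
    return float(round(float(x), 6))


def generate_kb(config: SimConfig) -> KnowledgeBase:
    """Generate a synthetic knowledge base, deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    n_f, n_d = config.n_findings, config.n_diseases

    findings: dict[str, FindingDef] = {}
    n_bundles = max(1, n_f // 40)
    core_ids = set(
        rng.choice(n_f, size=max(1, int(round(config.p_core * n_f))), replace=False)
    )
    kinds = rng.choice(["clinical", "lab", "imaging"], size=n_f, p=[0.6, 0.3, 0.1])
    costs = np.maximum(0.1, np.round(np.exp(rng.normal(0.0, 0.7, size=n_f)), 2))
    bundle_assign = rng.integers(0, n_bundles * 8, size=n_f)  # ~1 in 8 bundled
    for i in range(n_f):
        fid = f"f{i:04d}"
        bundle = f"b{bundle_assign[i]:03d}" if bundle_assign[i] < n_bundles else None
        findings[fid] = FindingDef(
            finding_id=fid,
            name=f"finding {i}",
            kind=str(kinds[i]),
            cost=_round6(costs[i]),
            bundle_id=bundle,
            is_core=i in core_ids,
        )
    finding_ids = sorted(findings)

    categories = {f"c{i:02d}": f"category {i}" for i in range(config.n_categories)}
    cat_ids = sorted(categories)

    mu, sigma = config.incidence_lognormal
    diseases: dict[str, Disease] = {}
    associations: dict[tuple[str, str], DiseaseFinding] = {}
    a, b = config.frequency_beta
    span_lo, span_hi = config.onset_span_years
    for j in range(n_d):
        did = f"d{j:04d}"
        # each disease has a typical manifestation age; its incidence
        # concentrates there and its findings' onset ages cluster around
        # it, as in real curated content (a childhood disease has
        # childhood onsets)
        manifest_age = float(rng.uniform(0.0, 60.0))
        lo_edge = _round6(max(0.5, manifest_age - 5.0))
        hi_edge = _round6(min(119.0, manifest_age + 25.0 + rng.uniform(0.0, 20.0)))
        edges = [0.0, lo_edge, hi_edge, MAX_AGE]
        n_bins = 3
        weights = rng.lognormal(mu, sigma, size=n_bins)
        weights[0] *= 0.05  # little incidence before the disease manifests
        weights[2] *= 0.2
        if rng.random() < 0.15:
            weights[rng.integers(0, n_bins)] = 0.0
        if not np.any(weights > 0):
            weights[1] = 1.0
        gm = rng.lognormal(0.0, 0.3, size=2)
        diseases[did] = Disease(
            disease_id=did,
            name=f"disease {j}",
            incidence=IncidenceProfile(
                age_bins=tuple(
                    (edges[k], edges[k + 1]) for k in range(n_bins)
                ),
                incidence_per_bin=tuple(_round6(w) for w in weights),
                gender_multiplier={
                    "male": _round6(gm[0]),
                    "female": _round6(gm[1]),
                },
            ),
            category_ids=frozenset(
                str(c)
                for c in rng.choice(cat_ids, size=int(rng.integers(1, 3)), replace=False)
            ),
            treatability=_round6(rng.beta(2, 2)),
            severity=_round6(rng.beta(2, 2)),
            heritable=bool(rng.random() < 0.3),
            acuity_class=str(rng.choice(ACUITY_CLASSES, p=[0.05, 0.1, 0.15, 0.2, 0.2, 0.2, 0.1])),
        )
        k = int(
            np.clip(rng.poisson(config.findings_per_disease_mean), 1, n_f)
        )
        chosen = rng.choice(n_f, size=k, replace=False)
        freqs = np.clip(rng.beta(a, b, size=k), 0.01, 1.0)
        onset_los = np.clip(
            manifest_age + rng.normal(0.0, 7.0, size=k), 0.0, MAX_AGE - 10.0
        )
        spans = rng.uniform(span_lo, span_hi, size=k)
        disap_draws = rng.random(size=k)
        disap_gaps = rng.uniform(1.0, 30.0, size=k)
        disap_spans = rng.uniform(span_lo, span_hi, size=k)
        for t in range(k):
            fid = finding_ids[int(chosen[t])]
            o_lo = _round6(onset_los[t])
            o_hi = _round6(min(onset_los[t] + spans[t], MAX_AGE))
            disappearance = None
            if disap_draws[t] < config.p_disappearance:
                d_lo = _round6(min(o_hi + disap_gaps[t], MAX_AGE))
                d_hi = _round6(min(d_lo + disap_spans[t], MAX_AGE))
                disappearance = (d_lo, d_hi)
            associations[(did, fid)] = DiseaseFinding(
                disease_id=did,
                finding_id=fid,
                frequency=_round6(freqs[t]),
                onset=(o_lo, o_hi),
                disappearance=disappearance,
            )

    return KnowledgeBase(
        findings=findings,
        diseases=diseases,
        associations=associations,
        categories=categories,
        core_checklist={finding_ids[i] for i in sorted(core_ids)},
    )


def _sample_age(rng: np.random.Generator, disease: Disease) -> float:
    prof = disease.incidence
    w = np.asarray(prof.incidence_per_bin, dtype=float)
    w = w / w.sum()
    k = int(rng.choice(len(w), p=w))
    lo, hi = prof.age_bins[k]
    return float(rng.uniform(lo, hi))


def _sample_ramp(rng: np.random.Generator, interval: tuple[float, float]) -> float:
    lo, hi = interval
    return lo if lo == hi else float(rng.uniform(lo, hi))


def simulate_patient(
    kb: KnowledgeBase,
    disease_id: str,
    config: SimConfig,
    seed: Optional[int] = None,
) -> tuple[PatientProfile, str]:
    """Simulate a patient with the given disease from the KB's own
    temporal model; returns (profile, true disease id).

    Each curated finding is present (with probability = its frequency)
    if its sampled onset age is at or below the patient's age and the
    sampled disappearance age (if any) has not passed; onset ages are
    recorded on present findings.  A Poisson(2)-sized sample of the
    remaining curated findings is recorded absent, as pertinent
    negatives.  Deterministic given the seed (default: config.seed).
    """
    if disease_id not in kb.diseases:
        raise KeyError(disease_id)
    assocs = sorted(
        kb.associations_for_disease(disease_id), key=lambda a: a.finding_id
    )
    if not assocs:
        raise ValueError(f"disease {disease_id} has no associations to simulate from")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    disease = kb.diseases[disease_id]
    age = round(_sample_age(rng, disease), 4)
    gm = disease.incidence.gender_multiplier
    total = sum(gm.values())
    gender = (
        "unspecified"
        if total <= 0
        else str(rng.choice(sorted(gm), p=[gm[g] / total for g in sorted(gm)]))
    )

    observations: list[Observation] = []
    absent_pool: list[str] = []
    for assoc in assocs:
        occurs = rng.random() < assoc.frequency
        onset = _sample_ramp(rng, assoc.onset)
        gone_at = (
            _sample_ramp(rng, assoc.disappearance)
            if assoc.disappearance is not None
            else None
        )
        present = occurs and onset <= age and (gone_at is None or age < gone_at)
        if present:
            observations.append(
                Observation(
                    finding_id=assoc.finding_id,
                    state="present",
                    onset_age=round(min(onset, age), 4),
                )
            )
        else:
            absent_pool.append(assoc.finding_id)
    n_neg = min(int(rng.poisson(2.0)), len(absent_pool))
    if n_neg > 0:
        negs = rng.choice(len(absent_pool), size=n_neg, replace=False)
        for i in sorted(int(x) for x in negs):
            observations.append(Observation(finding_id=absent_pool[i], state="absent"))

    acuity = disease.acuity_class if disease.acuity_class != "unknown" else None
    profile = PatientProfile(
        age=age,
        gender=gender if gender in ("male", "female") else "unspecified",
        observations=tuple(observations),
        acuity_observed=acuity,
    )
    return profile, disease_id


def corrupt_profile(
    profile: PatientProfile,
    noise: NoiseConfig,
    kb: KnowledgeBase,
    seed: int,
) -> PatientProfile:
    """Apply the four user-input-error modes independently per
    observation; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    observed = profile.observed_ids()
    unobserved = sorted(set(kb.findings) - observed)
    out: list[Observation] = []
    for obs in profile.observations:
        if rng.random() < noise.p_omit_finding:
            continue
        state, onset = obs.state, obs.onset_age
        if rng.random() < noise.p_misinterpret:
            state = "absent" if state == "present" else "present"
            onset = None
        if onset is not None and rng.random() < noise.p_drop_onset:
            onset = None
        out.append(Observation(finding_id=obs.finding_id, state=state, onset_age=onset))
        if unobserved and rng.random() < noise.p_spurious:
            pick = unobserved.pop(int(rng.integers(0, len(unobserved))))
            out.append(Observation(finding_id=pick, state="present"))
    return replace(profile, observations=tuple(out))
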