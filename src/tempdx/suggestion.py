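"""Cost- and urgency-weighted test suggestions by expected information gain.

For each finding the patient has not yet been asked about, the module
computes the expected reduction in Shannon entropy (bits) of the disease
posterior after learning whether the finding is present, using the
engine's own predictive distribution as the one-step lookahead.  Bundles
(findings reported together by a single test, e.g. the components of a
urinalysis) are scored as a joint observation over their outcome tree.
The gain is weighted up by the clinical urgency of the leading diseases
(their treatability, severity and acuity of onset) and divided by the
relative cost of the test, yielding a single usefulness score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

from .knowledge_base import ACUITY_SCALE, KnowledgeBase
from .temporal_bayes import (
    DEFAULT_PARAMS,
    Differential,
    EngineParams,
    PatientProfile,
    posterior,
    prob_present_at_age,
)

#: Bundles are scored over at most this many member findings; the
#: outcome tree grows as 2^k.
MAX_BUNDLE_MEMBERS = 4


@dataclass(frozen=True)
class SuggestionWeights:
    """Urgency weighting: w_t scales expected treatability, w_s expected
    severity, w_a the posterior mass on rapidly evolving diseases
    (acuity class of days or faster)."""

    w_t: float = 1.0
    w_s: float = 0.5
    w_a: float = 1.0


DEFAULT_WEIGHTS = SuggestionWeights()


@dataclass(frozen=True)
class Suggestion:
    target_id: str
    is_bundle: bool
    expected_gain: float  # bits
    urgency_weight: float
    cost: float
    usefulness: float
    members: tuple[str, ...] = ()


def entropy_bits(probs: Sequence[float]) -> float:
    return -sum(p * math.log2(p) for p in probs if p > 0.0)


def _presence_prob(
    kb: KnowledgeBase, disease_id: str, finding_id: str, age: float, params: EngineParams
) -> float:
    assoc = kb.get_association(disease_id, finding_id)
    if assoc is None:
        return params.f0
    return prob_present_at_age(assoc, age)


def predictive_presence(
    kb: KnowledgeBase,
    diff: Differential,
    finding_id: str,
    age: float,
    params: EngineParams = DEFAULT_PARAMS,
    observed: Optional[set[str]] = None,
) -> float:
    """Posterior-predictive probability that an unobserved finding is
    currently present: the posterior-weighted mixture of per-disease
    presence probabilities (background f0 for uncurated pairs)."""
    if observed and finding_id in observed:
        raise ValueError(f"finding {finding_id!r} already observed")
    return sum(
        p * _presence_prob(kb, did, finding_id, age, params) for did, p in diff.entries
    )


def _branch_posteriors(
    diff: Differential, pres_probs: dict[str, float], params: EngineParams
) -> tuple[float, float, float]:
    """Entropy after observing present / absent, and P(present).

    Uses the same eps_floor as the engine so lookahead matches what the
    engine would actually compute on the next visit.
    """
    w_pres, w_abs = [], []
    for did, p in diff.entries:
        q = pres_probs[did]
        w_pres.append(p * max(q, params.eps_floor))
        w_abs.append(p * max(1.0 - q, params.eps_floor))
    zp, za = sum(w_pres), sum(w_abs)
    h_pres = entropy_bits([w / zp for w in w_pres]) if zp > 0 else 0.0
    h_abs = entropy_bits([w / za for w in w_abs]) if za > 0 else 0.0
    p_plus = sum(p * pres_probs[did] for (did, p) in diff.entries)
    return h_pres, h_abs, p_plus


def expected_entropy_reduction(
    kb: KnowledgeBase,
    patient: PatientProfile,
    finding_id: str,
    params: EngineParams = DEFAULT_PARAMS,
    diff: Optional[Differential] = None,
) -> float:
    """Expected drop in posterior entropy (bits) from observing one
    finding; nonnegative by construction (clipped at 0)."""
    if finding_id in patient.observed_ids():
        raise ValueError(f"finding {finding_id!r} already observed")
    if diff is None:
        diff = posterior(kb, patient, params)
    pres = {
        did: _presence_prob(kb, did, finding_id, patient.age, params)
        for did, _ in diff.entries
    }
    h0 = entropy_bits([p for _, p in diff.entries])
    h_pres, h_abs, p_plus = _branch_posteriors(diff, pres, params)
    gain = h0 - (p_plus * h_pres + (1.0 - p_plus) * h_abs)
    return max(gain, 0.0)


def bundle_entropy_reduction(
    kb: KnowledgeBase,
    patient: PatientProfile,
    member_ids: Sequence[str],
    params: EngineParams = DEFAULT_PARAMS,
    diff: Optional[Differential] = None,
) -> float:
    """Expected gain of jointly observing a bundle's members, by
    enumerating the 2^k present/absent outcome tree (k <= 4)."""
    members = sorted(member_ids)[:MAX_BUNDLE_MEMBERS]
    if diff is None:
        diff = posterior(kb, patient, params)
    pres = {
        fid: {
            did: _presence_prob(kb, did, fid, patient.age, params)
            for did, _ in diff.entries
        }
        for fid in members
    }
    h0 = entropy_bits([p for _, p in diff.entries])
    expected = 0.0
    for outcome in product((True, False), repeat=len(members)):
        weights = []
        p_outcome = 0.0
        for did, p in diff.entries:
            lik = 1.0
            exact = 1.0
            for fid, is_present in zip(members, outcome):
                q = pres[fid][did]
                lik *= max(q if is_present else 1.0 - q, params.eps_floor)
                exact *= q if is_present else 1.0 - q
            weights.append(p * lik)
            p_outcome += p * exact
        z = sum(weights)
        if z <= 0.0 or p_outcome <= 0.0:
            continue
        expected += p_outcome * entropy_bits([w / z for w in weights])
    return max(h0 - expected, 0.0)


def urgency_weight(
    kb: KnowledgeBase,
    diff: Differential,
    weights: SuggestionWeights = DEFAULT_WEIGHTS,
) -> float:
    """1 + posterior-expected treatability, severity and acute-onset
    mass, each scaled by its weight.  Shared by every suggestion for a
    given differential: urgency reflects the diseases in play, not the
    test."""
    e_treat = e_sev = acute = 0.0
    for did, p in diff.entries:
        d = kb.diseases.get(did)
        if d is None:
            continue
        e_treat += p * d.treatability
        e_sev += p * d.severity
        if ACUITY_SCALE.get(d.acuity_class, 99) <= ACUITY_SCALE["days"]:
            acute += p
    return 1.0 + weights.w_t * e_treat + weights.w_s * e_sev + weights.w_a * acute


def rank_suggestions(
    kb: KnowledgeBase,
    patient: PatientProfile,
    params: EngineParams = DEFAULT_PARAMS,
    weights: SuggestionWeights = DEFAULT_WEIGHTS,
    top_n: Optional[int] = None,
) -> list[Suggestion]:
    """Rank every unobserved finding and every fully-unobserved bundle
    by usefulness = gain x urgency / cost, descending (ties by id)."""
    diff = posterior(kb, patient, params)
    observed = patient.observed_ids()
    urg = urgency_weight(kb, diff, weights)
    out: list[Suggestion] = []
    bundled_ids: set[str] = set()
    for bid in kb.bundle_ids():
        members = [m for m in kb.bundle_members(bid) if m not in observed]
        if not members:
            continue
        bundled_ids.update(members)
        cost = sum(kb.findings[m].cost for m in members)
        gain = bundle_entropy_reduction(kb, patient, members, params, diff)
        out.append(
            Suggestion(
                target_id=bid,
                is_bundle=True,
                expected_gain=gain,
                urgency_weight=urg,
                cost=cost,
                usefulness=gain * urg / cost,
                members=tuple(sorted(members)[:MAX_BUNDLE_MEMBERS]),
            )
        )
    for fid in sorted(kb.findings):
        if fid in observed or fid in bundled_ids:
            continue
        cost = kb.findings[fid].cost
        gain = expected_entropy_reduction(kb, patient, fid, params, diff)
        out.append(
            Suggestion(
                target_id=fid,
                is_bundle=False,
                expected_gain=gain,
                urgency_weight=urg,
                cost=cost,
                usefulness=gain * urg / cost,
            )
        )
    out.sort(key=lambda s: (-s.usefulness, s.target_id))
    return out[:top_n] if top_n is not None else out
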