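"""Curated disease-finding knowledge base: types, JSON I/O, validation, audits.

The knowledge base is the content model of a diagnostic decision-support
tool: a catalogue of findings (signs, symptoms, laboratory and imaging
observations, plus disease-acuity descriptors), a catalogue of diseases
with age/gender incidence profiles, and the disease-finding associations
that carry the temporal evidence model — how often a finding occurs in a
disease, over what age interval it appears, and (when applicable) over
what age interval it resolves.

Ages are real-valued years with birth at 0; incidence age bins tile
[0, 120).  All onset/disappearance intervals are closed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

MAX_AGE = 120.0

FINDING_KINDS = ("clinical", "lab", "imaging", "acuity")
ACUITY_CLASSES = ("minutes", "hours", "days", "weeks", "months", "years", "unknown")

#: Position of each acuity class on a log-time scale (minutes=0 ... years=5).
#: ``unknown`` is deliberately absent: diseases without curated acuity are
#: excluded from acuity matching.
ACUITY_SCALE = {"minutes": 0, "hours": 1, "days": 2, "weeks": 3, "months": 4, "years": 5}

#: Frequencies at or below this are read as "characteristically absent":
#: the finding was reviewed and recorded as a pertinent negative for the
#: disease rather than simply left uncurated.
NEAR_ZERO_FREQUENCY = 0.01


class KBError(ValueError):
    """Raised for malformed or invalid knowledge-base files."""


@dataclass(frozen=True)
class FindingDef:
    finding_id: str
    name: str
    kind: str = "clinical"
    cost: float = 1.0
    bundle_id: Optional[str] = None
    is_core: bool = False


@dataclass(frozen=True)
class IncidenceProfile:
    """Relative disease incidence by age bin and gender.

    ``age_bins`` are contiguous half-open ``[lo, hi)`` intervals covering
    [0, 120); ``incidence_per_bin`` are nonnegative relative weights (they
    need not sum to 1 — priors are normalized downstream).
    """

    age_bins: tuple[tuple[float, float], ...]
    incidence_per_bin: tuple[float, ...]
    gender_multiplier: Mapping[str, float] = field(
        default_factory=lambda: {"male": 1.0, "female": 1.0}
    )

    @staticmethod
    def uniform() -> "IncidenceProfile":
        return IncidenceProfile(age_bins=((0.0, MAX_AGE),), incidence_per_bin=(1.0,))


@dataclass(frozen=True)
class Disease:
    disease_id: str
    name: str
    incidence: IncidenceProfile
    category_ids: frozenset[str] = frozenset()
    treatability: float = 0.5
    severity: float = 0.5
    heritable: bool = False
    acuity_class: str = "unknown"


@dataclass(frozen=True)
class DiseaseFinding:
    """One curated disease-finding association.

    ``frequency`` is the probability the finding ever occurs in the
    disease; ``onset`` is the closed age interval over which it appears
    (linear ramp); ``disappearance``, if curated, the interval over which
    it resolves.
    """

    disease_id: str
    finding_id: str
    frequency: float
    onset: tuple[float, float]
    disappearance: Optional[tuple[float, float]] = None


@dataclass
class KnowledgeBase:
    findings: dict[str, FindingDef]
    diseases: dict[str, Disease]
    associations: dict[tuple[str, str], DiseaseFinding]
    categories: dict[str, str]
    core_checklist: set[str] = field(default_factory=set)

    # -- convenience lookups -------------------------------------------------
    def associations_for_disease(self, disease_id: str) -> list[DiseaseFinding]:
        return [a for a in self.associations.values() if a.disease_id == disease_id]

    def get_association(self, disease_id: str, finding_id: str) -> Optional[DiseaseFinding]:
        return self.associations.get((disease_id, finding_id))

    def bundle_members(self, bundle_id: str) -> list[str]:
        return sorted(
            f.finding_id for f in self.findings.values() if f.bundle_id == bundle_id
        )

    def bundle_ids(self) -> list[str]:
        return sorted({f.bundle_id for f in self.findings.values() if f.bundle_id})


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _finding_to_json(f: FindingDef) -> dict:
    d = {
        "finding_id": f.finding_id,
        "name": f.name,
        "kind": f.kind,
        "cost": f.cost,
        "is_core": f.is_core,
    }
    if f.bundle_id is not None:
        d["bundle_id"] = f.bundle_id
    return d


def _disease_to_json(d: Disease) -> dict:
    return {
        "disease_id": d.disease_id,
        "name": d.name,
        "category_ids": sorted(d.category_ids),
        "incidence": {
            "age_bins": [list(b) for b in d.incidence.age_bins],
            "incidence_per_bin": list(d.incidence.incidence_per_bin),
            "gender_multiplier": dict(sorted(d.incidence.gender_multiplier.items())),
        },
        "treatability": d.treatability,
        "severity": d.severity,
        "heritable": d.heritable,
        "acuity_class": d.acuity_class,
    }


def _assoc_to_json(a: DiseaseFinding) -> dict:
    d = {
        "disease_id": a.disease_id,
        "finding_id": a.finding_id,
        "frequency": a.frequency,
        "onset": list(a.onset),
    }
    if a.disappearance is not None:
        d["disappearance"] = list(a.disappearance)
    return d


def kb_to_json(kb: KnowledgeBase) -> dict:
    """Canonical JSON form: every list sorted by identifier."""
    return {
        "findings": [
            _finding_to_json(kb.findings[k]) for k in sorted(kb.findings)
        ],
        "diseases": [
            _disease_to_json(kb.diseases[k]) for k in sorted(kb.diseases)
        ],
        "associations": [
            _assoc_to_json(kb.associations[k]) for k in sorted(kb.associations)
        ],
        "categories": dict(sorted(kb.categories.items())),
        "core_checklist": sorted(kb.core_checklist),
    }


def canonical_serialization(kb: KnowledgeBase) -> str:
    return json.dumps(kb_to_json(kb), sort_keys=True, indent=1)


def save_kb(kb: KnowledgeBase, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(canonical_serialization(kb))
        fh.write("\n")


def _require(d: Mapping, key: str, where: str):
    if key not in d:
        raise KBError(f"{where}: missing required field '{key}'")
    return d[key]


def kb_from_json(doc: Mapping) -> KnowledgeBase:
    findings: dict[str, FindingDef] = {}
    for rec in _require(doc, "findings", "KB"):
        fid = _require(rec, "finding_id", "finding")
        findings[fid] = FindingDef(
            finding_id=fid,
            name=rec.get("name", fid),
            kind=rec.get("kind", "clinical"),
            cost=float(rec.get("cost", 1.0)),
            bundle_id=rec.get("bundle_id"),
            is_core=bool(rec.get("is_core", False)),
        )
    diseases: dict[str, Disease] = {}
    for rec in _require(doc, "diseases", "KB"):
        did = _require(rec, "disease_id", "disease")
        inc = _require(rec, "incidence", f"disease {did}")
        profile = IncidenceProfile(
            age_bins=tuple(tuple(float(x) for x in b) for b in inc["age_bins"]),
            incidence_per_bin=tuple(float(x) for x in inc["incidence_per_bin"]),
            gender_multiplier=dict(inc.get("gender_multiplier", {"male": 1.0, "female": 1.0})),
        )
        diseases[did] = Disease(
            disease_id=did,
            name=rec.get("name", did),
            category_ids=frozenset(rec.get("category_ids", [])),
            incidence=profile,
            treatability=float(rec.get("treatability", 0.5)),
            severity=float(rec.get("severity", 0.5)),
            heritable=bool(rec.get("heritable", False)),
            acuity_class=rec.get("acuity_class", "unknown"),
        )
    associations: dict[tuple[str, str], DiseaseFinding] = {}
    for rec in _require(doc, "associations", "KB"):
        did = _require(rec, "disease_id", "association")
        fid = _require(rec, "finding_id", "association")
        disap = rec.get("disappearance")
        associations[(did, fid)] = DiseaseFinding(
            disease_id=did,
            finding_id=fid,
            frequency=float(_require(rec, "frequency", f"association ({did},{fid})")),
            onset=tuple(float(x) for x in _require(rec, "onset", f"association ({did},{fid})")),
            disappearance=tuple(float(x) for x in disap) if disap is not None else None,
        )
    return KnowledgeBase(
        findings=findings,
        diseases=diseases,
        associations=associations,
        categories=dict(doc.get("categories", {})),
        core_checklist=set(doc.get("core_checklist", [])),
    )


def load_kb(path) -> KnowledgeBase:
    """Load and validate a knowledge base from its JSON file format.

    Raises :class:`KBError` naming the line for malformed JSON, or naming
    the offending record for a validation failure.
    """
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise KBError(f"{path}: malformed JSON at line {exc.lineno}: {exc.msg}") from exc
    kb = kb_from_json(doc)
    violations = validate_kb(kb)
    if violations:
        raise KBError(f"{path}: invalid knowledge base: " + "; ".join(violations[:5]))
    return kb


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _interval_ok(iv: Sequence[float]) -> bool:
    return len(iv) == 2 and math.isfinite(iv[0]) and math.isfinite(iv[1])


def validate_kb(kb: KnowledgeBase) -> list[str]:
    """Check every structural invariant; return violations as strings.

    An empty list means the KB is valid.  Each violation names the entity
    and the rule so curation errors can be located in the source file.
    """
    v: list[str] = []
    for f in kb.findings.values():
        if f.kind not in FINDING_KINDS:
            v.append(f"FindingDef.kind: {f.finding_id}: unknown kind '{f.kind}'")
        if not (f.cost >= 0.1):
            v.append(f"FindingDef.cost: {f.finding_id}: cost {f.cost} < 0.1")
    for d in kb.diseases.values():
        if not (0.0 <= d.treatability <= 1.0):
            v.append(f"Disease.treatability: {d.disease_id}: {d.treatability} outside [0,1]")
        if not (0.0 <= d.severity <= 1.0):
            v.append(f"Disease.severity: {d.disease_id}: {d.severity} outside [0,1]")
        if d.acuity_class not in ACUITY_CLASSES:
            v.append(f"Disease.acuity_class: {d.disease_id}: unknown class '{d.acuity_class}'")
        for cid in d.category_ids:
            if cid not in kb.categories:
                v.append(f"Disease.category_ids: {d.disease_id}: undeclared category '{cid}'")
        v.extend(_validate_incidence(d))
    for a in kb.associations.values():
        key = f"({a.disease_id},{a.finding_id})"
        if a.disease_id not in kb.diseases:
            v.append(f"DiseaseFinding.disease_id: {key}: dangling disease reference")
        if a.finding_id not in kb.findings:
            v.append(f"DiseaseFinding.finding_id: {key}: dangling finding reference")
        if not (0.0 < a.frequency <= 1.0):
            v.append(f"DiseaseFinding.frequency: {key}: {a.frequency} outside (0,1]")
        if not _interval_ok(a.onset) or a.onset[0] > a.onset[1]:
            v.append(f"DiseaseFinding.onset: {key}: onset interval reversed or malformed")
        if a.disappearance is not None:
            if not _interval_ok(a.disappearance) or a.disappearance[0] > a.disappearance[1]:
                v.append(f"DiseaseFinding.disappearance: {key}: interval reversed or malformed")
            elif _interval_ok(a.onset) and a.disappearance[1] < a.onset[0]:
                v.append(f"DiseaseFinding.disappearance: {key}: disappearance ends before onset begins")
    for fid in kb.core_checklist:
        if fid not in kb.findings:
            v.append(f"core_checklist: unknown finding '{fid}'")
    return v


def _validate_incidence(d: Disease) -> list[str]:
    v: list[str] = []
    prof = d.incidence
    bins = prof.age_bins
    if len(bins) != len(prof.incidence_per_bin):
        v.append(f"IncidenceProfile: {d.disease_id}: bin/weight length mismatch")
        return v
    if not bins:
        v.append(f"IncidenceProfile: {d.disease_id}: no age bins")
        return v
    if bins[0][0] != 0.0 or bins[-1][1] != MAX_AGE:
        v.append(f"IncidenceProfile: {d.disease_id}: bins do not cover [0,{MAX_AGE:g})")
    for (lo, hi) in bins:
        if lo >= hi:
            v.append(f"IncidenceProfile: {d.disease_id}: empty bin [{lo},{hi})")
    for (_, hi), (lo2, _) in zip(bins, bins[1:]):
        if hi != lo2:
            v.append(f"IncidenceProfile: {d.disease_id}: bins not contiguous at {hi}")
    if any(w < 0 for w in prof.incidence_per_bin):
        v.append(f"IncidenceProfile: {d.disease_id}: negative incidence weight")
    if not any(w > 0 for w in prof.incidence_per_bin):
        v.append(f"IncidenceProfile: {d.disease_id}: all bin weights zero")
    if any(m < 0 for m in prof.gender_multiplier.values()):
        v.append(f"IncidenceProfile: {d.disease_id}: negative gender multiplier")
    return v


# ---------------------------------------------------------------------------
# Completeness audit
# ---------------------------------------------------------------------------


def completeness_report(
    kb: KnowledgeBase,
    checklist: Optional[Iterable[str]] = None,
    scope: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Audit checklist coverage per disease, least complete first.

    For each disease in ``scope`` (default: all diseases) counts how many
    of the checklist findings carry an explicit association.  Two counts
    are reported because a curation review can require either an explicit
    frequency for every checklist item or merely a reviewed yes/no:
    ``n_checklist_annotated`` counts any association (including near-zero
    "characteristically absent" entries), ``n_checklist_positive`` only
    associations with frequency above the near-zero threshold.
    ``fraction`` is annotated / checklist size.
    """
    check = set(checklist) if checklist is not None else set(kb.core_checklist)
    if not check:
        raise ValueError("checklist must be nonempty")
    scope_ids = sorted(scope) if scope is not None else sorted(kb.diseases)
    rows = []
    for did in scope_ids:
        annotated = {
            a.finding_id
            for a in kb.associations.values()
            if a.disease_id == did and a.finding_id in check
        }
        positive = {
            a.finding_id
            for a in kb.associations.values()
            if a.disease_id == did
            and a.finding_id in check
            and a.frequency > NEAR_ZERO_FREQUENCY
        }
        rows.append(
            {
                "disease_id": did,
                "n_checklist_annotated": len(annotated),
                "n_checklist_positive": len(positive),
                "fraction": len(annotated) / len(check),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["disease_id", "n_checklist_annotated", "n_checklist_positive", "fraction"],
    )
    return df.sort_values(["fraction", "disease_id"], kind="stable").reset_index(drop=True)
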