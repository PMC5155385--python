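import pytest
from hypothesis import HealthCheck, settings

from tempdx.knowledge_base import (
    Disease,
    DiseaseFinding,
    FindingDef,
    IncidenceProfile,
    KnowledgeBase,
)
from tempdx.synthetic import SimConfig, generate_kb

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_toy_kb() -> KnowledgeBase:
    """Tiny hand-built KB: 3 diseases, 5 findings, a urinalysis bundle."""
    findings = {
        f.finding_id: f
        for f in [
            FindingDef("fever", "fever", "clinical", 1.0),
            FindingDef("rash", "rash", "clinical", 1.0),
            FindingDef("anemia", "anemia", "lab", 2.0),
            FindingDef("proteinuria", "proteinuria", "lab", 0.5, bundle_id="urinalysis"),
            FindingDef("hematuria", "hematuria", "lab", 0.5, bundle_id="urinalysis"),
        ]
    }
    uniform = IncidenceProfile.uniform()
    diseases = {
        "dA": Disease("dA", "disease A", uniform, frozenset({"arthritis"}),
                      treatability=0.9, severity=0.7, acuity_class="days"),
        "dB": Disease("dB", "disease B", uniform, frozenset({"arthritis", "vasculitis"}),
                      treatability=0.3, severity=0.4, acuity_class="years"),
        "dC": Disease("dC", "disease C", uniform, frozenset({"vasculitis"}),
                      treatability=0.5, severity=0.5, acuity_class="unknown"),
    }
    assoc_list = [
        DiseaseFinding("dA", "fever", 0.8, (2.0, 6.0)),
        DiseaseFinding("dA", "rash", 1.0, (0.0, 0.0), (10.0, 20.0)),
        DiseaseFinding("dA", "proteinuria", 0.6, (0.0, 5.0)),
        DiseaseFinding("dB", "fever", 0.5, (0.0, 10.0)),
        DiseaseFinding("dB", "anemia", 0.9, (0.0, 0.0)),
        DiseaseFinding("dB", "hematuria", 0.4, (1.0, 3.0)),
        DiseaseFinding("dC", "rash", 0.7, (0.0, 2.0)),
    ]
    return KnowledgeBase(
        findings=findings,
        diseases=diseases,
        associations={(a.disease_id, a.finding_id): a for a in assoc_list},
        categories={"arthritis": "arthritis", "vasculitis": "vasculitis"},
        core_checklist={"fever", "rash"},
    )


@pytest.fixture
def toy_kb() -> KnowledgeBase:
    return make_toy_kb()


@pytest.fixture(scope="session")
def small_random_kb() -> KnowledgeBase:
    """50-disease synthetic KB shared across tests (read-only)."""
    return generate_kb(SimConfig(seed=11, n_diseases=50, n_findings=120))


@pytest.fixture(scope="session")
def ten_disease_kb() -> KnowledgeBase:
    return generate_kb(SimConfig(seed=7, n_diseases=10, n_findings=40))
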