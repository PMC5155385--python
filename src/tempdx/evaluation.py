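"""Study-evaluation metrics for paired differential-diagnosis logs.

A validation study of a diagnostic decision-support tool asks testers to
produce a ranked differential diagnosis for each case vignette twice:
once unaided ("baseline") and once after using the tool ("aided").
Against an expert gold standard (proven diagnosis ranked #1), this
module computes:

* **diagnostic error** — the tester's differential contains neither the
  correct diagnosis nor any of its disease categories;
* **relevance** — the fraction of the tester's listed diagnoses that
  also appear in the gold-standard differential;
* **change classification** — whether the aided pass fixed an error,
  added one, or left the instance unchanged;
* **group aggregation** — error counts and rates, percent of changes
  that reduced errors, and the relative decrease in error rate, by
  specialty, seniority, case or tester (percentages rounded half-up to
  match conventional reporting);
* **GEE analysis** — a marginal logistic regression of the binary error
  outcome on study phase with testers as clusters (each tester
  contributes 16 correlated instances), exchangeable working
  correlation and robust (sandwich) standard errors, with Wald
  chi-square tests.

``build_fixture_log`` turns published margin counts (errors / fixed /
added per tester group or per case) into a concrete synthetic response
log whose aggregation reproduces those margins exactly, so the study's
printed arithmetic can be recomputed end to end.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

SPECIALTIES = ("pediatrics", "emergency", "rheumatology")
SENIORITIES = ("junior", "senior")
PHASES = ("baseline", "aided")

CHANGE_CLASSES = ("fixed_error", "added_error", "unchanged_correct", "unchanged_error")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (82.5 -> 83), as used in printed tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _norm(token: str) -> str:
    return token.strip().lower()


@dataclass(frozen=True)
class GoldStandard:
    case_id: str
    correct_diagnosis: str
    correct_categories: frozenset[str] = frozenset()
    gold_differential: tuple[str, ...] = ()
    gold_workup: tuple[str, ...] = ()

    def __post_init__(self):
        if self.gold_differential and _norm(self.gold_differential[0]) != _norm(
            self.correct_diagnosis
        ):
            raise ValueError(
                f"gold standard for {self.case_id}: correct diagnosis must rank #1"
            )


@dataclass(frozen=True)
class ResponseRecord:
    tester_id: str
    specialty: str
    seniority: str
    case_id: str
    phase: str
    differential: tuple[str, ...]
    workup: tuple[str, ...] = ()

    def __post_init__(self):
        if self.specialty not in SPECIALTIES:
            raise ValueError(f"unknown specialty {self.specialty!r}")
        if self.seniority not in SENIORITIES:
            raise ValueError(f"unknown seniority {self.seniority!r}")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if not self.differential:
            raise ValueError("differential must be nonempty")


@dataclass(frozen=True)
class ResponsePair:
    baseline: ResponseRecord
    aided: ResponseRecord

    def __post_init__(self):
        if (
            self.baseline.tester_id != self.aided.tester_id
            or self.baseline.case_id != self.aided.case_id
        ):
            raise ValueError("baseline/aided records must share tester and case")
        if self.baseline.phase != "baseline" or self.aided.phase != "aided":
            raise ValueError("pair phases must be (baseline, aided)")


# ---------------------------------------------------------------------------
# Core metrics
# ---------------------------------------------------------------------------


def is_error(record: ResponseRecord, gold: GoldStandard) -> bool:
    """True iff the differential omits both the correct diagnosis and
    every one of its categories."""
    if record.case_id != gold.case_id:
        raise ValueError(
            f"case mismatch: record {record.case_id} vs gold {gold.case_id}"
        )
    listed = {_norm(x) for x in record.differential}
    if _norm(gold.correct_diagnosis) in listed:
        return False
    if any(_norm(c) in listed for c in gold.correct_categories):
        return False
    return True


def relevance(record: ResponseRecord, gold: GoldStandard) -> float:
    """Fraction of the tester's listed diagnoses that appear in the
    gold-standard differential."""
    if record.case_id != gold.case_id:
        raise ValueError("case mismatch")
    if not record.differential:
        raise ValueError("empty differential")
    gold_set = {_norm(x) for x in gold.gold_differential}
    listed = [_norm(x) for x in record.differential]
    return sum(1 for x in listed if x in gold_set) / len(listed)


def classify_change(
    baseline: ResponseRecord, aided: ResponseRecord, gold: GoldStandard
) -> str:
    pair = ResponsePair(baseline, aided)  # validates the pairing
    be = is_error(pair.baseline, gold)
    ae = is_error(pair.aided, gold)
    if be and not ae:
        return "fixed_error"
    if not be and ae:
        return "added_error"
    return "unchanged_error" if be else "unchanged_correct"


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

_GROUP_FIELDS = {
    "specialty": lambda p: p.baseline.specialty,
    "seniority": lambda p: p.baseline.seniority,
    "case": lambda p: p.baseline.case_id,
    "tester": lambda p: p.baseline.tester_id,
    "all": lambda p: "all",
}


def _group_label(pair: ResponsePair, group_by) -> str:
    if isinstance(group_by, str):
        return _GROUP_FIELDS[group_by](pair)
    return "/".join(_GROUP_FIELDS[g](pair) for g in group_by)


def aggregate(
    pairs: Sequence[ResponsePair],
    gold: Mapping[str, GoldStandard],
    group_by="all",
) -> pd.DataFrame:
    """Error/change counts and the printed-style percentages per group.

    ``group_by`` is one of specialty, seniority, case, tester, all — or
    a tuple of those for cross-classification.  Percentages are rounded
    half-up to integers; percent-of-changes-improving is NaN when a
    group made no changes.
    """
    counts: dict[str, dict[str, int]] = {}
    for pair in pairs:
        g = gold[pair.baseline.case_id]
        label = _group_label(pair, group_by)
        c = counts.setdefault(
            label,
            {"n_instances": 0, "baseline_errors": 0, "fixed_errors": 0, "added_errors": 0},
        )
        c["n_instances"] += 1
        change = classify_change(pair.baseline, pair.aided, g)
        if is_error(pair.baseline, g):
            c["baseline_errors"] += 1
        if change == "fixed_error":
            c["fixed_errors"] += 1
        elif change == "added_error":
            c["added_errors"] += 1
    rows = []
    for label in sorted(counts):
        c = counts[label]
        aided_errors = c["baseline_errors"] - c["fixed_errors"] + c["added_errors"]
        changes = c["fixed_errors"] + c["added_errors"]
        rows.append(
            {
                "group": label,
                **c,
                "aided_errors": aided_errors,
                "pct_changes_improving": (
                    round_half_up(100.0 * c["fixed_errors"] / changes)
                    if changes
                    else math.nan
                ),
                "baseline_error_rate_pct": round_half_up(
                    100.0 * c["baseline_errors"] / c["n_instances"]
                ),
                "aided_error_rate_pct": round_half_up(
                    100.0 * aided_errors / c["n_instances"]
                ),
                "relative_decrease_pct": (
                    round_half_up(
                        100.0
                        * (c["baseline_errors"] - aided_errors)
                        / c["baseline_errors"]
                    )
                    if c["baseline_errors"]
                    else math.nan
                ),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def differential_size_stats(
    pairs: Sequence[ResponsePair], gold: Mapping[str, GoldStandard]
) -> pd.DataFrame:
    """Mean and median differential length by change stratum and phase.

    Strata: all instances that did not end in error ("all"), those
    correct in both phases ("unchanged_correct"), and fixed errors.
    """
    strata: dict[str, list[ResponsePair]] = {"all": [], "unchanged_correct": [], "fixed_error": []}
    for pair in pairs:
        g = gold[pair.baseline.case_id]
        change = classify_change(pair.baseline, pair.aided, g)
        if change in ("unchanged_correct", "fixed_error"):
            strata["all"].append(pair)
            strata[change].append(pair)
    rows = []
    for name, members in strata.items():
        for phase in PHASES:
            lengths = [
                len((p.baseline if phase == "baseline" else p.aided).differential)
                for p in members
            ]
            rows.append(
                {
                    "stratum": name,
                    "phase": phase,
                    "n": len(lengths),
                    "mean": float(np.mean(lengths)) if lengths else math.nan,
                    "median": float(np.median(lengths)) if lengths else math.nan,
                }
            )
    return pd.DataFrame(rows).set_index(["stratum", "phase"])


# ---------------------------------------------------------------------------
# GEE analysis
# ---------------------------------------------------------------------------


@dataclass
class GEEResult:
    """Marginal logistic-regression results with cluster-robust inference."""

    params: pd.Series
    robust_se: pd.Series
    wald_chi2: pd.Series
    p_values: pd.Series
    alpha: float  # exchangeable working-correlation estimate
    n_clusters: int
    converged: bool
    model_description: str = ""

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "robust_se": self.robust_se,
                "wald_chi2": self.wald_chi2,
                "p_value": self.p_values,
            }
        )


def gee_logistic(
    outcomes: Sequence[int],
    design: pd.DataFrame,
    clusters: Sequence,
    correlation: str = "exchangeable",
    add_intercept: bool = True,
    maxiter: int = 60,
) -> GEEResult:
    """Fit a logistic GEE for a clustered binary outcome.

    Uses an exchangeable working correlation (moment estimate of the
    within-cluster correlation) and the robust sandwich covariance;
    each coefficient's Wald statistic (coef/SE)^2 is referred to a
    1-df chi-square.  ``correlation='independence'`` gives the
    ordinary logistic score equations with robust errors.
    """
    y = np.asarray(outcomes, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcomes must be binary")
    groups = pd.Series(list(clusters))
    if groups.nunique() < 2:
        raise ValueError("need at least 2 clusters")
    X = design.copy()
    if add_intercept and "const" not in X.columns:
        X = sm.add_constant(X, has_constant="add")
    if correlation == "exchangeable":
        cov_struct = sm.cov_struct.Exchangeable()
    elif correlation == "independence":
        cov_struct = sm.cov_struct.Independence()
    else:
        raise ValueError(f"unknown working correlation {correlation!r}")
    model = sm.GEE(y, X, groups=groups, family=sm.families.Binomial(), cov_struct=cov_struct)
    try:
        res = model.fit(maxiter=maxiter)
        converged = bool(getattr(res, "converged", True))
    except Exception as exc:  # separation / non-convergence must be explicit
        raise RuntimeError(f"GEE did not converge: {exc}") from exc
    params = pd.Series(res.params, index=X.columns)
    se = pd.Series(res.bse, index=X.columns)
    wald = (params / se) ** 2
    from scipy import stats

    pvals = pd.Series(stats.chi2.sf(wald, df=1), index=X.columns)
    alpha = (
        float(np.atleast_1d(cov_struct.dep_params)[0])
        if correlation == "exchangeable"
        else 0.0
    )
    return GEEResult(
        params=params,
        robust_se=se,
        wald_chi2=wald,
        p_values=pvals,
        alpha=alpha,
        n_clusters=int(groups.nunique()),
        converged=converged,
        model_description=f"logit link, {correlation} working correlation",
    )


def gee_phase_effect(pairs: Sequence[ResponsePair], gold: Mapping[str, GoldStandard]) -> GEEResult:
    """The study's primary contrast: error ~ phase, clustered by tester."""
    y, phase, cluster = [], [], []
    for pair in pairs:
        g = gold[pair.baseline.case_id]
        for rec in (pair.baseline, pair.aided):
            y.append(int(is_error(rec, g)))
            phase.append(int(rec.phase == "aided"))
            cluster.append(rec.tester_id)
    design = pd.DataFrame({"phase_aided": phase})
    return gee_logistic(y, design, cluster)


# ---------------------------------------------------------------------------
# Fixture logs from printed margins
# ---------------------------------------------------------------------------

#: Tester roster of the validation study: 26 testers, 13 junior / 13
#: senior, split 7 general pediatrics / 9 emergency medicine / 10
#: pediatric rheumatology.
DEFAULT_ROSTER: tuple[tuple[str, str, str], ...] = tuple(
    (f"t{i + 1:02d}", seniority, specialty)
    for i, (seniority, specialty) in enumerate(
        [("junior", "pediatrics")] * 3
        + [("junior", "emergency")] * 5
        + [("junior", "rheumatology")] * 5
        + [("senior", "pediatrics")] * 4
        + [("senior", "emergency")] * 4
        + [("senior", "rheumatology")] * 5
    )
)

DEFAULT_CASE_IDS = ("1184", "2088", "3613", "4967", "5615", "6295", "7870", "8434")

#: Margin counts (baseline errors, fixed errors, added errors) by tester
#: group, as printed in the study's change-by-tester table.
TABLE4_MARGINS: dict[tuple[str, str], tuple[int, int, int]] = {
    ("junior", "rheumatology"): (5, 4, 0),
    ("junior", "emergency"): (13, 10, 0),
    ("junior", "pediatrics"): (8, 6, 2),
    ("senior", "rheumatology"): (4, 1, 0),
    ("senior", "emergency"): (13, 8, 2),
    ("senior", "pediatrics"): (15, 4, 3),
}

#: Margin counts by case (26 instances each), change-by-case table.
TABLE5_MARGINS: dict[str, tuple[int, int, int]] = {
    "1184": (19, 8, 1),
    "6295": (15, 10, 0),
    "3613": (8, 3, 2),
    "2088": (4, 3, 0),
    "8434": (4, 3, 0),
    "7870": (3, 2, 1),
    "5615": (3, 3, 2),
    "4967": (2, 1, 1),
}


def default_gold_set(case_ids: Iterable[str] = DEFAULT_CASE_IDS) -> dict[str, GoldStandard]:
    return {
        c: GoldStandard(
            case_id=c,
            correct_diagnosis=f"dx_{c}",
            correct_categories=frozenset({f"cat_{c}"}),
            gold_differential=(f"dx_{c}", f"alt1_{c}", f"alt2_{c}"),
        )
        for c in case_ids
    }


def _make_record(tester, case_id, phase, error: bool) -> ResponseRecord:
    tid, seniority, specialty = tester
    differential = (
        (f"miss1_{case_id}", f"miss2_{case_id}")
        if error
        else (f"dx_{case_id}", f"alt1_{case_id}")
    )
    return ResponseRecord(
        tester_id=tid,
        specialty=specialty,
        seniority=seniority,
        case_id=case_id,
        phase=phase,
        differential=differential,
    )


def _allocate(
    instances: list[tuple],
    margin: tuple[int, int, int],
    label: str,
) -> list[ResponsePair]:
    """Greedy deterministic allocation of (error, fixed, added) states
    over a block of tester x case instances, in tester-id order."""
    baseline_errors, fixed, added = margin
    n = len(instances)
    if not (0 <= fixed <= baseline_errors <= n):
        raise ValueError(
            f"{label}: inconsistent margins (need fixed <= baseline errors <= {n})"
        )
    if added > n - baseline_errors:
        raise ValueError(f"{label}: added errors exceed correct baseline instances")
    pairs = []
    for idx, (tester, case_id) in enumerate(instances):
        b_err = idx < baseline_errors
        if b_err:
            a_err = idx >= fixed  # first `fixed` error instances get corrected
        else:
            a_err = idx < baseline_errors + added
        pairs.append(
            ResponsePair(
                _make_record(tester, case_id, "baseline", b_err),
                _make_record(tester, case_id, "aided", a_err),
            )
        )
    return pairs


def build_fixture_log(
    margins: Mapping,
    layout: str,
    roster: Sequence[tuple[str, str, str]] = DEFAULT_ROSTER,
    case_ids: Sequence[str] = DEFAULT_CASE_IDS,
) -> tuple[list[ResponsePair], dict[str, GoldStandard]]:
    """Build a deterministic synthetic response log realizing printed
    margin counts.

    ``layout='by_group'``: margins keyed by (seniority, specialty);
    every tester in a group contributes len(case_ids) instances.
    ``layout='by_case'``: margins keyed by case id; every case has one
    instance per tester.  Raises on internally inconsistent margins.
    """
    gold = default_gold_set(case_ids)
    pairs: list[ResponsePair] = []
    if layout == "by_group":
        for key in sorted(margins):
            seniority, specialty = key
            members = [t for t in roster if t[1] == seniority and t[2] == specialty]
            if not members:
                raise ValueError(f"no testers in roster for group {key}")
            instances = [(t, c) for t in members for c in case_ids]
            pairs.extend(_allocate(instances, margins[key], f"group {key}"))
    elif layout == "by_case":
        for case_id in sorted(margins):
            if case_id not in case_ids:
                raise ValueError(f"margin case {case_id!r} not in case list")
            instances = [(t, case_id) for t in roster]
            pairs.extend(_allocate(instances, margins[case_id], f"case {case_id}"))
    else:
        raise ValueError("layout must be 'by_group' or 'by_case'")
    return pairs, gold


# ---------------------------------------------------------------------------
# Log / gold I/O (TSV + JSON external formats)
# ---------------------------------------------------------------------------


def write_log(pairs: Sequence[ResponsePair], path) -> None:
    rows = []
    for pair in pairs:
        for rec in (pair.baseline, pair.aided):
            rows.append(
                {
                    "tester_id": rec.tester_id,
                    "specialty": rec.specialty,
                    "seniority": rec.seniority,
                    "case_id": rec.case_id,
                    "phase": rec.phase,
                    "differential": ";".join(rec.differential),
                    "workup": ";".join(rec.workup),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_log(path) -> list[ResponsePair]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records: dict[tuple[str, str, str], ResponseRecord] = {}
    for _, row in df.iterrows():
        rec = ResponseRecord(
            tester_id=row["tester_id"],
            specialty=row["specialty"],
            seniority=row["seniority"],
            case_id=row["case_id"],
            phase=row["phase"],
            differential=tuple(x for x in row["differential"].split(";") if x),
            workup=tuple(x for x in row["workup"].split(";") if x),
        )
        key = (rec.tester_id, rec.case_id, rec.phase)
        if key in records:
            raise ValueError(f"duplicate record for {key}")
        records[key] = rec
    pairs = []
    for (tid, cid, phase), rec in sorted(records.items()):
        if phase != "baseline":
            continue
        aided = records.get((tid, cid, "aided"))
        if aided is None:
            raise ValueError(f"missing aided record for tester {tid}, case {cid}")
        pairs.append(ResponsePair(rec, aided))
    return pairs


def read_gold(path) -> dict[str, GoldStandard]:
    with open(path, "r", encoding="utf-8") as fh:
        docs = json.load(fh)
    gold = {}
    for d in docs:
        gold[d["case_id"]] = GoldStandard(
            case_id=d["case_id"],
            correct_diagnosis=d["correct_diagnosis"],
            correct_categories=frozenset(d.get("correct_categories", [])),
            gold_differential=tuple(d.get("gold_differential", [])),
            gold_workup=tuple(d.get("gold_workup", [])),
        )
    return gold


def write_gold(gold: Mapping[str, GoldStandard], path) -> None:
    docs = [
        {
            "case_id": g.case_id,
            "correct_diagnosis": g.correct_diagnosis,
            "correct_categories": sorted(g.correct_categories),
            "gold_differential": list(g.gold_differential),
            "gold_workup": list(g.gold_workup),
        }
        for _, g in sorted(gold.items())
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(docs, fh, indent=1, sort_keys=True)
        fh.write("\n")
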