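"""Engine tests: priors, temporal likelihoods, posterior, categories.

The posterior is cross-checked against an exact-rational-arithmetic
oracle that recomputes the naive-Bayes product with ``fractions``;
the per-observation likelihood against an independent straight-line
transcription of the branch formulas; onset-window masses against
numeric quadrature of the ramp density.
"""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

from tempdx.knowledge_base import Disease, DiseaseFinding, IncidenceProfile
from tempdx.synthetic import SimConfig, generate_kb, simulate_patient
from tempdx.temporal_bayes import (
    DEFAULT_PARAMS,
    EngineParams,
    Observation,
    PatientProfile,
    acuity_likelihood,
    expand_categories,
    observation_likelihood,
    onset_bin_mass,
    posterior,
    prior_weight,
    prob_present_at_age,
    ramp_cdf,
)

# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------


class TestPriorWeight:
    def test_uniform_profile_is_one_everywhere(self):
        d = Disease("d", "d", IncidenceProfile.uniform())
        for age in (0.0, 8.0, 119.9, 120.0):
            assert prior_weight(d, age) == 1.0

    def test_prior_ratio_follows_bin_weights(self):
        prof = lambda w: IncidenceProfile(
            age_bins=((0.0, 120.0),), incidence_per_bin=(w,)
        )
        a = prior_weight(Disease("a", "a", prof(2.0)), 8.0)
        b = prior_weight(Disease("b", "b", prof(1.0)), 8.0)
        assert a / b == pytest.approx(2.0)

    def test_unspecified_gender_averages_multipliers(self):
        prof = IncidenceProfile(
            age_bins=((0.0, 120.0),),
            incidence_per_bin=(1.0,),
            gender_multiplier={"male": 2.0, "female": 1.0},
        )
        d = Disease("d", "d", prof)
        assert prior_weight(d, 5.0, "male") == 2.0
        assert prior_weight(d, 5.0, "female") == 1.0
        assert prior_weight(d, 5.0, "unspecified") == pytest.approx(1.5)

    def test_matches_linear_scan_oracle_on_random_profiles(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n_bins = rng.integers(1, 6)
            cuts = np.sort(rng.uniform(0.5, 119.5, size=n_bins - 1))
            edges = [0.0, *cuts.tolist(), 120.0]
            weights = rng.uniform(0, 5, size=n_bins)
            prof = IncidenceProfile(
                age_bins=tuple((edges[i], edges[i + 1]) for i in range(n_bins)),
                incidence_per_bin=tuple(weights),
            )
            d = Disease("d", "d", prof)
            for age in rng.uniform(0, 119.99, size=30):
                expected = None
                for (lo, hi), w in zip(prof.age_bins, prof.incidence_per_bin):
                    if lo <= age < hi:
                        expected = w
                assert prior_weight(d, age) == pytest.approx(expected)

    def test_age_not_covered_raises(self):
        prof = IncidenceProfile(age_bins=((0.0, 10.0),), incidence_per_bin=(1.0,))
        with pytest.raises(ValueError, match="age not covered"):
            prior_weight(Disease("d", "d", prof), 50.0)


# ---------------------------------------------------------------------------
# Temporal likelihood primitives
# ---------------------------------------------------------------------------


class TestProbPresent:
    @pytest.mark.parametrize(
        "freq,onset,disappearance,age,expected",
        [
            (0.8, (2.0, 6.0), None, 6.0, 0.8),       # ramp completed
            (0.8, (2.0, 6.0), None, 4.0, 0.4),       # midpoint of onset ramp
            (1.0, (0.0, 0.0), (10.0, 20.0), 15.0, 0.5),  # midpoint of disappearance
            (0.8, (2.0, 6.0), None, 1.0, 0.0),       # before onset
            (1.0, (0.0, 0.0), (10.0, 20.0), 25.0, 0.0),  # fully disappeared
        ],
    )
    def test_ramp_formula(self, freq, onset, disappearance, age, expected):
        assoc = DiseaseFinding("d", "f", freq, onset, disappearance)
        assert prob_present_at_age(assoc, age) == pytest.approx(expected)


class TestOnsetBinMass:
    def test_uniform_ramp_density_times_width(self):
        assoc = DiseaseFinding("d", "f", 1.0, (0.0, 10.0))
        assert onset_bin_mass(assoc, 5.0, 0.5) == pytest.approx(0.05)

    def test_point_onset_is_unit_mass_in_any_window(self):
        assoc = DiseaseFinding("d", "f", 1.0, (4.0, 4.0))
        for w in (0.1, 0.25, 3.0):
            assert onset_bin_mass(assoc, 4.0, w) == 1.0
        assert onset_bin_mass(assoc, 10.0, 0.25) == 0.0

    def test_matches_quadrature_of_ramp_density(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            lo = rng.uniform(0, 50)
            hi = lo + rng.uniform(0.5, 20)
            assoc = DiseaseFinding("d", "f", 1.0, (lo, hi))
            onset_age = rng.uniform(lo - 2, hi + 2)
            width = rng.uniform(0.05, 2.0)
            density = 1.0 / (hi - lo)
            expected, _ = quad(
                lambda x: density if lo <= x <= hi else 0.0,
                onset_age - width / 2,
                onset_age + width / 2,
                points=[lo, hi] if lo < hi else None,
                limit=200,
            )
            got = onset_bin_mass(assoc, onset_age, width)
            assert got == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# Observation likelihood: dual-implementation oracle
# ---------------------------------------------------------------------------


def _likelihood_oracle(kb, disease_id, obs, age, params):
    """Straight transcription of the branch formulas, written separately
    from the engine path."""
    assoc = kb.associations.get((disease_id, obs.finding_id))
    if assoc is None:
        if obs.state == "absent":
            val = 1.0 - params.f0
        elif obs.onset_age is None:
            val = params.f0
        else:
            val = min(params.f0 * params.bin_width / age, params.f0) if age > 0 else params.f0
    else:
        freq = assoc.frequency
        p_on = ramp_cdf(age, assoc.onset[0], assoc.onset[1])
        p_gone = (
            ramp_cdf(age, assoc.disappearance[0], assoc.disappearance[1])
            if assoc.disappearance
            else 0.0
        )
        if obs.state == "absent":
            val = 1.0 - freq * p_on * (1.0 - p_gone)
        elif obs.onset_age is None:
            val = freq * p_on * (1.0 - p_gone)
        else:
            val = freq * onset_bin_mass(assoc, obs.onset_age, params.bin_width) * (1.0 - p_gone)
    return max(val, params.eps_floor)


class TestObservationLikelihood:
    def test_contradicted_certain_finding_hits_floor(self, toy_kb):
        obs = Observation("rash", "absent")
        # rash in dA: frequency 1.0, onset [0,0]; at age 5 it must be present
        lik = observation_likelihood(toy_kb, "dA", obs, 5.0)
        assert lik == DEFAULT_PARAMS.eps_floor

    def test_absent_is_complement_of_presence(self, toy_kb):
        obs = Observation("fever", "absent")
        # dA fever: 0.8 x ramp(4; 2,6) = 0.4 present -> 0.6 absent
        assert observation_likelihood(toy_kb, "dA", obs, 4.0) == pytest.approx(0.6)

    def test_unknown_finding_raises(self, toy_kb):
        with pytest.raises(KeyError):
            observation_likelihood(toy_kb, "dA", Observation("nope", "present"), 4.0)

    def test_agrees_with_independent_transcription(self, small_random_kb):
        kb = small_random_kb
        rng = np.random.default_rng(21)
        dids = sorted(kb.diseases)
        fids = sorted(kb.findings)
        params = EngineParams()
        for _ in range(300):
            did = dids[rng.integers(len(dids))]
            fid = fids[rng.integers(len(fids))]
            age = float(rng.uniform(0, 120))
            state = "present" if rng.random() < 0.6 else "absent"
            onset = (
                float(rng.uniform(0, age)) if state == "present" and rng.random() < 0.5 else None
            )
            obs = Observation(fid, state, onset)
            got = observation_likelihood(kb, did, obs, age, params)
            assert got == pytest.approx(
                _likelihood_oracle(kb, did, obs, age, params), rel=1e-12
            )


# ---------------------------------------------------------------------------
# Posterior
# ---------------------------------------------------------------------------


def _posterior_oracle(kb, patient, params):
    """Exact naive-Bayes posterior via rational arithmetic."""
    scores = {}
    for did, disease in kb.diseases.items():
        prior = prior_weight(disease, patient.age, patient.gender)
        if prior <= 0:
            continue
        score = Fraction(prior)
        for obs in patient.observations:
            score *= Fraction(observation_likelihood(kb, did, obs, patient.age, params))
        if patient.acuity_observed is not None:
            score *= Fraction(acuity_likelihood(disease, patient.acuity_observed, params))
        scores[did] = score
    z = sum(scores.values())
    return {did: s / z for did, s in scores.items()}


class TestPosterior:
    def test_two_disease_normalization_arithmetic(self, toy_kb):
        # present rash at age 5: certain (and not yet disappearing) in dA,
        # completed ramp 0.7 in dC, uncurated in dB (f0)
        patient = PatientProfile(age=5.0, observations=(Observation("rash", "present"),))
        diff = posterior(toy_kb, patient)
        post = diff.as_dict()
        f0 = DEFAULT_PARAMS.f0
        z = 1.0 + 0.7 + f0
        assert post["dA"] == pytest.approx(1.0 / z, abs=1e-12)
        assert post["dB"] == pytest.approx(f0 / z, abs=1e-12)

    def test_no_observations_recovers_normalized_prior(self, toy_kb):
        diff = posterior(toy_kb, PatientProfile(age=30.0))
        for _, p in diff.entries:
            assert p == pytest.approx(1.0 / 3.0)

    def test_all_priors_zero_raises(self, toy_kb):
        prof = IncidenceProfile(
            age_bins=((0.0, 10.0), (10.0, 120.0)), incidence_per_bin=(1.0, 0.0)
        )
        for did in list(toy_kb.diseases):
            d = toy_kb.diseases[did]
            toy_kb.diseases[did] = Disease(did, d.name, prof, d.category_ids)
        with pytest.raises(ValueError, match="no admissible disease"):
            posterior(toy_kb, PatientProfile(age=50.0))

    def test_matches_exact_rational_oracle(self, ten_disease_kb):
        kb = ten_disease_kb
        rng = np.random.default_rng(3)
        fids = sorted(kb.findings)
        for trial in range(20):
            age = float(rng.uniform(1, 100))
            chosen = rng.choice(len(fids), size=5, replace=False)
            obs = []
            for i in chosen:
                state = "present" if rng.random() < 0.6 else "absent"
                onset = (
                    round(float(rng.uniform(0, age)), 3)
                    if state == "present" and rng.random() < 0.5
                    else None
                )
                obs.append(Observation(fids[int(i)], state, onset))
            patient = PatientProfile(age=age, observations=tuple(obs))
            diff = posterior(kb, patient)
            oracle = _posterior_oracle(kb, patient, DEFAULT_PARAMS)
            for did, p in diff.entries:
                assert abs(p - float(oracle.get(did, 0.0))) < 1e-9

    def test_normalization_and_sort_order(self, small_random_kb):
        kb = small_random_kb
        rng = np.random.default_rng(8)
        fids = sorted(kb.findings)
        for _ in range(50):
            age = float(rng.uniform(0, 119))
            obs = tuple(
                Observation(fids[int(i)], "present" if rng.random() < 0.5 else "absent")
                for i in rng.choice(len(fids), size=6, replace=False)
            )
            diff = posterior(kb, PatientProfile(age=age, observations=obs))
            assert abs(sum(p for _, p in diff.entries) - 1.0) < 1e-9
            probs = [p for _, p in diff.entries]
            assert probs == sorted(probs, reverse=True)

    def test_order_invariance_of_observations(self, toy_kb):
        obs = (
            Observation("fever", "present", 3.0),
            Observation("rash", "absent"),
            Observation("anemia", "present"),
        )
        p1 = posterior(toy_kb, PatientProfile(age=5.0, observations=obs))
        p2 = posterior(toy_kb, PatientProfile(age=5.0, observations=obs[::-1]))
        assert p1.entries == p2.entries

    @given(freq_a=st.floats(0.05, 1.0), freq_b=st.floats(0.05, 1.0),
           age=st.floats(1.0, 100.0))
    def test_pertinent_negative_lowers_odds_of_disease_expecting_finding(
        self, freq_a, freq_b, age
    ):
        """Recording a finding absent shifts odds against the disease in
        which it is more probable at that age."""
        kb = make_two_disease_kb(freq_a, freq_b)
        base = posterior(kb, PatientProfile(age=age)).as_dict()
        neg = posterior(
            kb,
            PatientProfile(age=age, observations=(Observation("f", "absent"),)),
        ).as_dict()
        pa = prob_present_at_age(kb.associations[("a", "f")], age)
        pb = prob_present_at_age(kb.associations[("b", "f")], age)
        odds_before = base["a"] / base["b"]
        odds_after = neg["a"] / neg["b"]
        if pa > pb and (1 - pa) > DEFAULT_PARAMS.eps_floor:
            assert odds_after < odds_before
        elif pa == pb:
            assert odds_after == pytest.approx(odds_before)

    def test_onset_age_sharpens_odds_toward_matching_interval(self):
        """A present finding with a recorded onset inside one disease's
        onset interval and outside the other's raises the matching
        disease's odds at least as much as the undated observation."""
        kb = make_two_disease_kb(0.8, 0.8, onset_a=(2.0, 4.0), onset_b=(20.0, 40.0))
        age = 50.0
        undated = posterior(
            kb, PatientProfile(age=age, observations=(Observation("f", "present"),))
        ).as_dict()
        dated = posterior(
            kb,
            PatientProfile(age=age, observations=(Observation("f", "present", 3.0),)),
        ).as_dict()
        assert dated["a"] / dated["b"] >= undated["a"] / undated["b"]


def make_two_disease_kb(freq_a, freq_b, onset_a=(0.0, 10.0), onset_b=(0.0, 10.0)):
    from tempdx.knowledge_base import FindingDef, KnowledgeBase

    uniform = IncidenceProfile.uniform()
    return KnowledgeBase(
        findings={"f": FindingDef("f", "f")},
        diseases={
            "a": Disease("a", "a", uniform),
            "b": Disease("b", "b", uniform),
        },
        associations={
            ("a", "f"): DiseaseFinding("a", "f", freq_a, onset_a),
            ("b", "f"): DiseaseFinding("b", "f", freq_b, onset_b),
        },
        categories={},
    )


# ---------------------------------------------------------------------------
# Acuity and categories
# ---------------------------------------------------------------------------


class TestAcuity:
    def test_match_near_far_and_neutral(self, toy_kb):
        p = DEFAULT_PARAMS
        assert acuity_likelihood(toy_kb.diseases["dA"], "days", p) == p.acuity_match
        assert acuity_likelihood(toy_kb.diseases["dA"], "weeks", p) == p.acuity_near
        assert acuity_likelihood(toy_kb.diseases["dA"], "years", p) == p.acuity_far
        assert acuity_likelihood(toy_kb.diseases["dC"], "days", p) == 1.0  # unknown class

    def test_observed_acuity_shifts_posterior(self, toy_kb):
        base = posterior(toy_kb, PatientProfile(age=30.0)).as_dict()
        acute = posterior(toy_kb, PatientProfile(age=30.0, acuity_observed="days")).as_dict()
        assert acute["dA"] > base["dA"]  # dA evolves over days
        assert acute["dB"] < base["dB"]  # dB evolves over years


class TestExpandCategories:
    def test_single_disease_mass(self, toy_kb):
        patient = PatientProfile(
            age=5.0,
            observations=(
                Observation("rash", "present"),
                Observation("proteinuria", "present"),
                Observation("anemia", "absent"),
            ),
        )
        diff = posterior(toy_kb, patient)
        cats = dict(expand_categories(toy_kb, diff))
        post = diff.as_dict()
        assert cats["arthritis"] == pytest.approx(post["dA"] + post["dB"])
        assert cats["vasculitis"] == pytest.approx(post["dB"] + post["dC"])

    def test_matches_brute_force_group_by(self, small_random_kb):
        kb = small_random_kb
        diff = posterior(kb, PatientProfile(age=40.0))
        cats = dict(expand_categories(kb, diff))
        brute = {}
        for did, p in diff.entries:
            for cid in kb.diseases[did].category_ids:
                brute[cid] = brute.get(cid, 0.0) + p
        assert set(cats) == set(brute)
        for cid in brute:
            assert cats[cid] == pytest.approx(brute[cid])
        masses = [m for _, m in expand_categories(kb, diff)]
        assert masses == sorted(masses, reverse=True)


class TestGenerativeRecovery:
    def test_true_disease_ranks_well_from_noise_free_simulations(self, small_random_kb):
        """Patients simulated from a disease should place it near the
        top of the posterior (sanity check on a 50-disease KB; the full
        200-disease check lives in the acceptance suite)."""
        kb = small_random_kb
        cfg = SimConfig(seed=11, n_diseases=50, n_findings=120)
        rng = np.random.default_rng(17)
        dids = sorted(kb.diseases)
        hits = 0
        n = 100
        for i in range(n):
            did = dids[int(rng.integers(len(dids)))]
            profile, truth = simulate_patient(kb, did, cfg, seed=int(rng.integers(2**31)))
            diff = posterior(kb, profile)
            if diff.rank_of(truth) <= 5:
                hits += 1
        assert hits / n >= 0.90
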