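import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linkaudit import ConfigError
from linkaudit.engines import (
    IDENTITY_CALIBRATION,
    MonotoneCalibration,
    RuleMatchOutcome,
    SOUNDEX_SENTINEL,
    ThresholdSet,
    WeightTable,
    calibrate_scores,
    pprl_match,
    rule_match,
    rule_match_registry,
    soundex,
    token_similarity,
)
from linkaudit.tokens import DEFAULT_SCHEMA, normalize_pii, tokenize_registry


# --- independent soundex oracle: NARA formulation (drop H/W, digit-encode
# including vowels as 0, collapse runs, strip zeros) -------------------------
_ORACLE_CODES = {c: d for letters, d in
                 (("BFPV", "1"), ("CGJKQSXZ", "2"), ("DT", "3"),
                  ("L", "4"), ("MN", "5"), ("R", "6"))
                 for c in letters}


def soundex_oracle(name: str) -> str:
    letters = [c for c in name.upper() if c.isalpha()]
    if not letters:
        return SOUNDEX_SENTINEL
    first = letters[0]
    tail = [c for c in letters[1:] if c not in "HW"]
    digits = [_ORACLE_CODES.get(c, "0") for c in tail]
    collapsed = []
    prev = _ORACLE_CODES.get(first, "0")
    for d in digits:
        if d != prev:
            collapsed.append(d)
        prev = d
    return (first + "".join(d for d in collapsed if d != "0") + "000")[:4]


class TestSoundex:
    @pytest.mark.parametrize("name,code", [
        ("Robert", "R163"),
        ("Rupert", "R163"),
        ("Tymczak", "T522"),
        ("Pfister", "P236"),
        ("Ashcraft", "A261"),
        ("Honeyman", "H555"),
        ("R", "R000"),
    ])
    def test_known_codes_match_oracle(self, name, code):
        assert soundex_oracle(name) == code  # oracle sanity
        assert soundex(name) == code

    def test_empty_input_gives_sentinel(self):
        assert soundex("") == SOUNDEX_SENTINEL
        assert soundex("123!") == SOUNDEX_SENTINEL

    def test_case_insensitive(self):
        assert soundex("smith") == soundex("SMITH")

    @given(st.text(alphabet=st.characters(min_codepoint=65, max_codepoint=122),
                   min_size=1, max_size=15))
    @settings(max_examples=300, deadline=None)
    def test_agrees_with_independent_oracle(self, name):
        assert soundex(name) == soundex_oracle(name)

    @given(st.text(alphabet="abcdefghijklmnopqrstuvwxyz", min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_output_shape(self, name):
        code = soundex(name)
        assert len(code) == 4
        assert code[0].isalpha() and code[1:].isdigit()


def _record(record_id="Q1", **overrides):
    base = {
        "record_id": record_id,
        "first_name": "maria",
        "middle_name": "luz",
        "last_name": "garcia",
        "gender": "f",
        "dob": "03/04/1985",
        "ssn": "987654321",
        "phone": "3105550000",
        "email": "maria@example.com",
        "street_address": "10 elm st",
        "zip": "90001",
    }
    base.update(overrides)
    return base


class TestRuleMatch:
    def test_identical_candidate_matches(self):
        out = rule_match(_record(), [_record("C1")], WeightTable())
        assert out.matched and out.matched_record_id == "C1"

    def test_two_qualifying_candidates_is_unsuccessful(self):
        out = rule_match(_record(), [_record("C1"), _record("C2")], WeightTable())
        assert out.status == "unsuccessful" and out.matched_record_id is None

    def test_all_below_threshold_is_unsuccessful(self):
        cand = _record("C1", first_name="zoe", last_name="quist", dob="01/01/1999",
                       email="", phone="", street_address="", zip="", ssn="")
        out = rule_match(_record(), [cand], WeightTable())
        assert out.status == "unsuccessful"

    def test_empty_candidate_set_is_unsuccessful(self):
        assert rule_match(_record(), [], WeightTable()).status == "unsuccessful"

    def test_threshold_is_strict_inequality(self):
        # craft a candidate scoring exactly the threshold: dob(30)+yob(10)+
        # email(15)+zip(5) = 60
        weights = WeightTable(match_threshold=60.0)
        cand = _record("C1", first_name="zz", last_name="yy", gender="m",
                       phone="", street_address="", middle_name="q")
        out = rule_match(_record(), [cand], weights)
        assert out.points == 60.0
        assert out.status == "unsuccessful"

    def test_missing_fields_never_agree(self):
        q = _record(email="", phone="")
        c = _record("C1", email="", phone="")
        out_full = rule_match(_record(), [_record("C1")], WeightTable())
        out_miss = rule_match(q, [c], WeightTable())
        assert out_miss.points == out_full.points - 30  # email 15 + phone 15

    def test_invalid_weight_table(self):
        with pytest.raises(ConfigError):
            WeightTable(weights={"exact_height": 5.0})
        with pytest.raises(ConfigError):
            WeightTable(match_threshold=0)

    def test_registry_blocking_agrees_with_direct_matching(self, small_registries):
        _, reg_a, reg_b, _, _ = small_registries
        queries = [normalize_pii(r) for r in reg_a.head(120).to_dict("records")]
        cands = [normalize_pii(r) for r in reg_b.head(400).to_dict("records")]
        weights = WeightTable()
        blocked = rule_match_registry(queries, cands, weights)
        direct = [rule_match(q, cands, weights) for q in queries]
        for b, d in zip(blocked, direct):
            assert (b.status, b.matched_record_id) == (d.status, d.matched_record_id)


class TestTokenSimilarity:
    def test_identical_arrays(self):
        a = ["h1", "h2", "h3"]
        assert token_similarity(a, list(a)) == 1.0

    def test_fully_disjoint(self):
        assert token_similarity(["x", "y"], ["p", "q"]) == 0.0

    def test_six_of_ten_matches_set_based_oracle(self):
        # 6 agreeing templates, 4 present on one side only -> union of 10
        a = [f"t{i}" for i in range(6)] + ["a7", "a8", None, None]
        b = [f"t{i}" for i in range(6)] + [None, None, "b9", "b10"]
        # brute-force set-based Jaccard over (position, value) pairs
        sa = {(i, v) for i, v in enumerate(a) if v is not None}
        sb = {(i, v) for i, v in enumerate(b) if v is not None}
        oracle = len(sa & sb) / len(sa | sb)
        assert oracle == 0.6
        assert token_similarity(a, b) == pytest.approx(0.6)

    def test_disagreeing_template_counts_once_in_denominator(self):
        a = ["same", "diff_a"]
        b = ["same", "diff_b"]
        assert token_similarity(a, b) == pytest.approx(0.5)

    def test_both_null_templates_ignored(self):
        assert token_similarity(["x", None], ["x", None]) == 1.0

    def test_all_null_union_is_zero(self):
        assert token_similarity([None, None], [None, None]) == 0.0

    def test_weighted(self):
        a = ["x", "y"]
        b = ["x", "z"]
        assert token_similarity(a, b, [3.0, 1.0]) == pytest.approx(0.75)

    def test_schema_mismatch_raises(self):
        with pytest.raises(ConfigError):
            token_similarity(["x"], ["x", "y"])
        with pytest.raises(ConfigError):
            token_similarity(["x"], ["y"], [1.0, 1.0])

    @given(st.lists(st.sampled_from(["u", "v", "w", None]), min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_symmetry_and_range(self, arr):
        rng = np.random.default_rng(0)
        other = [None if v is None and rng.random() < 0.5 else
                 rng.choice(["u", "v", None]) for v in arr]
        s1 = token_similarity(arr, other)
        s2 = token_similarity(other, arr)
        assert s1 == s2
        assert 0.0 <= s1 <= 1.0


class TestCalibration:
    def test_monotone_and_bounded(self):
        raw = [0.1, 0.2, 0.5, 0.8, 0.9, 1.0]
        labels = [0, 0, 0, 1, 1, 1]
        cal = calibrate_scores(raw, labels)
        xs = np.linspace(0, 1, 101)
        scores = cal.score(xs)
        assert np.all(np.diff(scores) >= -1e-9)
        assert scores.min() >= 0 and scores.max() <= 100

    def test_separable_labels_stay_separated(self):
        rng = np.random.default_rng(1)
        raw_false = rng.uniform(0.0, 0.4, 200)
        raw_true = rng.uniform(0.6, 1.0, 200)
        cal = calibrate_scores(np.r_[raw_false, raw_true],
                               np.r_[np.zeros(200), np.ones(200)])
        assert cal.score(raw_true).min() > cal.score(raw_false).max()

    def test_single_class_rejected(self):
        with pytest.raises(ConfigError):
            calibrate_scores([0.2, 0.9], [1, 1])

    def test_raw_one_scores_at_least_everything_below(self):
        rng = np.random.default_rng(2)
        raw = rng.uniform(0, 1, 500)
        labels = (raw > 0.5).astype(int)
        cal = calibrate_scores(raw, labels)
        top = cal.score(1.0)
        assert np.all(cal.score(raw) <= top + 1e-9)

    def test_heldout_precision_tracks_score_cutoff(self):
        # P(true | raw) = raw by construction; calibrated empirical precision at
        # the score-s cutoff should be ~ s/100 or better, within binomial error.
        rng = np.random.default_rng(3)
        raw_train = rng.uniform(0, 1, 4000)
        y_train = (rng.uniform(0, 1, 4000) < raw_train).astype(int)
        cal = calibrate_scores(raw_train, y_train)
        raw_test = rng.uniform(0, 1, 20000)
        y_test = (rng.uniform(0, 1, 20000) < raw_test).astype(int)
        scores = cal.score(raw_test)
        for cutoff in (90.0, 95.0):
            sel = scores >= cutoff
            assert sel.sum() > 100
            prec = y_test[sel].mean()
            se = np.sqrt(prec * (1 - prec) / sel.sum())
            assert prec >= cutoff / 100 - 3 * se - 0.02

    def test_serialization_roundtrip(self):
        cal = calibrate_scores([0.1, 0.4, 0.9, 1.0], [0, 0, 1, 1])
        back = MonotoneCalibration.from_dict(cal.to_dict())
        xs = np.linspace(0, 1, 50)
        assert np.allclose(back.score(xs), cal.score(xs))


class TestThresholdSet:
    def test_default_family(self):
        t = ThresholdSet()
        assert (t.strict, t.balanced, t.permissive) == (98.0, 95.0, 90.0)

    def test_ordering_enforced(self):
        with pytest.raises(ConfigError):
            ThresholdSet(strict=90, balanced=95, permissive=98)


class TestPPRLMatch:
    def _tokens(self, registries, n=None):
        _, reg_a, reg_b, truth, _ = registries
        if n is not None:
            reg_a, reg_b = reg_a.head(n), reg_b.head(n)
        tok_a, _ = tokenize_registry(reg_a, DEFAULT_SCHEMA, "s")
        tok_b, _ = tokenize_registry(reg_b, DEFAULT_SCHEMA, "s")
        return tok_a, tok_b, truth

    def test_containment_structural(self, small_registries):
        tok_a, tok_b, _ = self._tokens(small_registries, n=300)
        res = pprl_match(tok_a, tok_b)
        assert res.match_sets["strict"] <= res.match_sets["balanced"]
        assert res.match_sets["balanced"] <= res.match_sets["permissive"]

    def test_perfect_data_recovers_truth(self, clean_registries):
        tok_a, tok_b, truth = self._tokens(clean_registries)
        res = pprl_match(tok_a, tok_b)
        truth_pairs = set(zip(truth["record_id_site_a"], truth["record_id_site_b"]))
        assert res.match_sets["permissive"] == truth_pairs
        assert res.match_sets["strict"] == truth_pairs

    def test_blocking_equals_all_pairs_on_200_record_fixture(self, small_registries):
        tok_a, tok_b, _ = self._tokens(small_registries, n=200)
        blocked = pprl_match(tok_a, tok_b, blocking=True)
        exhaustive = pprl_match(tok_a, tok_b, blocking=False)
        assert blocked.assignment.equals(exhaustive.assignment)
        assert blocked.match_sets == exhaustive.match_sets

    def test_one_to_one(self, small_registries):
        tok_a, tok_b, _ = self._tokens(small_registries, n=400)
        res = pprl_match(tok_a, tok_b)
        a_ids = res.assignment["record_id_a"]
        b_ids = res.assignment["record_id_b"]
        assert a_ids.is_unique and b_ids.is_unique

    def test_deterministic(self, small_registries):
        tok_a, tok_b, _ = self._tokens(small_registries, n=300)
        r1 = pprl_match(tok_a, tok_b)
        r2 = pprl_match(tok_a, tok_b)
        assert r1.assignment.equals(r2.assignment)
        assert r1.match_sets == r2.match_sets

    def test_empty_candidates(self):
        cols = ["record_id", *DEFAULT_SCHEMA.template_ids]
        empty = pd.DataFrame(columns=cols)
        res = pprl_match(empty, empty)
        assert all(len(s) == 0 for s in res.match_sets.values())

    def test_blocking_never_drops_positive_similarity_pair(self, small_registries):
        # any agreement implies a shared token value, hence a shared block
        tok_a, tok_b, _ = self._tokens(small_registries, n=150)
        blocked = pprl_match(tok_a, tok_b, blocking=True)
        exhaustive = pprl_match(tok_a, tok_b, blocking=False)
        pairs_b = set(zip(blocked.scored_pairs["record_id_a"],
                          blocked.scored_pairs["record_id_b"]))
        pairs_e = set(zip(exhaustive.scored_pairs["record_id_a"],
                          exhaustive.scored_pairs["record_id_b"]))
        assert pairs_b == pairs_e
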