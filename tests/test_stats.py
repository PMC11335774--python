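"""Derived statistics: lemma/relative frequencies, N-grams, ambiguity,
orthographic neighborhood."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lexstat import (
    CoreFeatures,
    LexiconDB,
    NeighborhoodParams,
    annotate_ngrams,
    build_ngram_tables,
    compute_ambform,
    compute_amblemma,
    compute_lemma_freq,
    compute_neighborhood,
    compute_posx,
    db_from_spec,
    random_corpus_spec,
    relative,
)
from lexstat.stats import UndefinedDatabaseError


def form_db(**forms):
    """A database of single-reading NOUN entries: form -> frequency."""
    db = LexiconDB()
    for form, freq in forms.items():
        db.add(form, "NOUN", form, CoreFeatures(), freq)
    return db


class TestLemmaFreq:
    def test_single_entry(self):
        db = LexiconDB()
        db.add("a", "NOUN", "x", CoreFeatures(), 5)
        assert compute_lemma_freq(db) == {("a", "NOUN"): 5}

    def test_table4_sums_to_printed_total(self, table4_db):
        assert compute_lemma_freq(table4_db)[("voi", "NOUN")] == 156_925

    def test_lemmas_sharing_a_form_stay_independent(self):
        db = LexiconDB()
        db.add("a", "NOUN", "f", CoreFeatures(), 3)
        db.add("b", "VERB", "f", CoreFeatures(), 4)
        assert compute_lemma_freq(db) == {("a", "NOUN"): 3, ("b", "VERB"): 4}


class TestPosx:
    @pytest.mark.parametrize("pos, expected", [("AUX", "VERB"), ("VERB", "VERB"), ("NOUN", "NOUN")])
    def test_mapping(self, pos, expected):
        assert compute_posx(pos) == expected


class TestRelative:
    @pytest.mark.parametrize(
        "raw, total, expected",
        [(50, 2_000_000, 25.0), (0, 123, 0.0), (77, 77, 1_000_000.0)],
    )
    def test_per_million(self, raw, total, expected):
        assert relative(raw, total) == expected

    def test_zero_total_undefined(self):
        with pytest.raises(UndefinedDatabaseError):
            relative(1, 0)

    @given(st.integers(1, 10**6), st.integers(1, 10**9))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_strictly_increasing_in_raw(self, raw, total):
        assert relative(raw, total) < relative(raw + 1, total)


class TestNgramTables:
    def test_bigram_enumeration_token_weighted(self):
        tables = build_ngram_tables(form_db(aalto=10))
        assert dict(tables.bigram) == {"aa": 10, "al": 10, "lt": 10, "to": 10}

    def test_initial_trigrams(self):
        tables = build_ngram_tables(form_db(aurinko=5, auto=3))
        assert tables.initial_trigram["aur"] == 5
        assert tables.initial_trigram["aut"] == 3
        assert tables.final_trigram["nko"] == 5 and tables.final_trigram["uto"] == 3

    def test_length_two_form_has_no_trigram_contribution(self):
        tables = build_ngram_tables(form_db(ab=9))
        assert dict(tables.bigram) == {"ab": 9}
        assert not tables.initial_trigram and not tables.final_trigram

    def test_form_frequency_summed_across_readings(self):
        db = form_db(voi=10)
        db.add("voida", "VERB", "voi", CoreFeatures(tense="Pres"), 30)
        tables = build_ngram_tables(db)
        assert tables.bigram["vo"] == 40

    def test_conservation_over_random_db(self):
        db = db_from_spec(random_corpus_spec(11, 80))
        tables = build_ngram_tables(db)
        from lexstat.stats import compute_form_freq

        long_mass = sum(n for f, n in compute_form_freq(db).items() if len(f) >= 3)
        assert sum(tables.initial_trigram.values()) == long_mass
        assert sum(tables.final_trigram.values()) == long_mass


class TestAnnotateNgrams:
    def test_single_bigram(self):
        tables = build_ngram_tables(form_db(ab=7))
        assert annotate_ngrams("ab", tables).bigramfreq == 7.0

    def test_mean_of_enumerated_counts(self):
        db = form_db(ab=4, bc=6)
        features = annotate_ngrams("abc", build_ngram_tables(db))
        assert features.bigramfreq == 5.0

    def test_trigram_features_absent_below_length_four(self):
        tables = build_ngram_tables(form_db(abc=5, abcd=5))
        short = annotate_ngrams("abc", tables)
        assert short.initrigramfreq is None and short.fintrigramfreq is None
        long = annotate_ngrams("abcd", tables)
        # length-3 forms still feed the tables even though they carry no feature
        assert long.initrigramfreq == 10

    def test_relative_scaling(self):
        tables = build_ngram_tables(form_db(abcd=10))
        tables.scaling_base = 1_000_000  # with a 1M-token base, rel == raw
        features = annotate_ngrams("abcd", tables)
        assert features.relinitrigramfreq == features.initrigramfreq

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            annotate_ngrams("a", build_ngram_tables(form_db(ab=1)))


class TestAmbform:
    def test_table3_printed_values(self, table3_db):
        amb = compute_ambform(table3_db)
        assert round(amb[("voi", "INTJ", "voi")], 3) == 0.954
        assert round(amb[("voi", "NOUN", "voi")], 3) == 0.997

    def test_sole_owner_is_unambiguous(self):
        amb = compute_ambform(form_db(auto=100))
        assert amb[("auto", "NOUN", "auto")] == 0.0

    def test_two_owner_shares(self):
        db = LexiconDB()
        db.add("a", "NOUN", "f", CoreFeatures(), 60)
        db.add("b", "VERB", "f", CoreFeatures(), 40)
        amb = compute_ambform(db)
        assert math.isclose(amb[("a", "NOUN", "f")], 0.400)
        assert math.isclose(amb[("b", "VERB", "f")], 0.600)

    def test_same_value_across_feature_rows(self, table3_db):
        """All three voida feature rows of the form share one ambform."""
        amb = compute_ambform(table3_db)
        assert len({k for k in amb if k[0] == "voida"}) == 1

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_partition_and_range_properties(self, seed):
        db = db_from_spec(random_corpus_spec(seed, 60))
        amb = compute_ambform(db)
        assert all(0.0 <= v <= 1.0 for v in amb.values())
        by_form = {}
        for (l, p, f), v in amb.items():
            by_form.setdefault(f, []).append(v)
        for shares in by_form.values():
            assert math.isclose(sum(1.0 - v for v in shares), 1.0, abs_tol=1e-9)

    def test_monotonicity_in_own_frequency(self):
        def amb_at(freq):
            db = LexiconDB()
            db.add("a", "NOUN", "f", CoreFeatures(), freq)
            db.add("b", "VERB", "f", CoreFeatures(), 50)
            return compute_ambform(db)[("a", "NOUN", "f")]

        values = [amb_at(n) for n in (1, 10, 100, 1000)]
        assert values == sorted(values, reverse=True)


class TestAmblemma:
    def test_interjection_with_single_ambiguous_form(self, table3_db):
        amb = compute_ambform(table3_db)
        aml = compute_amblemma(table3_db, amb)
        assert aml[("voi", "INTJ")] == 1.0

    def test_all_forms_unambiguous_gives_zero(self):
        db = form_db(auto=50, kissa=30)  # each form has a single owner
        aml = compute_amblemma(db, compute_ambform(db))
        assert set(aml.values()) == {0.0}

    def test_table4_weighted_indicator_sum(self, table4_db):
        """Treating the printed rows as the noun's complete form set, with the
        printed ambform column, only voissa (0.002) is below the 1% threshold."""
        printed_ambform = {
            ("voi", "NOUN", "voita"): 0.504,
            ("voi", "NOUN", "voi"): 0.997,
            ("voi", "NOUN", "voin"): 0.984,
            ("voi", "NOUN", "voissa"): 0.002,
            ("voi", "NOUN", "voilla"): 0.026,
            ("voi", "NOUN", "voista"): 0.033,
        }
        aml = compute_amblemma(table4_db, printed_ambform)
        assert math.isclose(aml[("voi", "NOUN")], (156_925 - 13_453) / 156_925)
        assert round(aml[("voi", "NOUN")], 3) == 0.914

    def test_threshold_is_inclusive_at_boundary(self):
        db = LexiconDB()
        db.add("a", "NOUN", "f", CoreFeatures(), 99)
        db.add("b", "VERB", "f", CoreFeatures(), 1)
        amb = compute_ambform(db)  # ambform(a) == 0.01 exactly
        aml = compute_amblemma(db, amb, threshold=0.01)
        assert aml[("a", "NOUN")] == 1.0

    def test_invalid_threshold(self, table3_db):
        with pytest.raises(ValueError):
            compute_amblemma(table3_db, compute_ambform(table3_db), threshold=0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_values_in_unit_interval(self, seed):
        db = db_from_spec(random_corpus_spec(seed, 50))
        aml = compute_amblemma(db, compute_ambform(db))
        assert all(0.0 <= v <= 1.0 for v in aml.values())


def brute_force_hood(db, params):
    """O(n^2) pairwise Hamming-distance-1 count with the inclusion filter."""
    from lexstat.stats import compute_form_freq

    freq = compute_form_freq(db)
    forms = sorted(freq)
    out = {}
    for w in forms:
        count = 0
        for v in forms:
            if v == w or len(v) != len(w):
                continue
            if sum(a != b for a, b in zip(v, w)) == 1 and params.includes(v, freq[v]):
                count += 1
        out[w] = count
    return out


class TestNeighborhood:
    def test_single_form_has_empty_hood(self):
        assert compute_neighborhood(form_db(auto=10)) == {"auto": 0}

    def test_filter_rules_worked_example(self):
        db = form_db(talo=20_000, tali=15_000, talk=50, tale=500)
        params = NeighborhoodParams(validity_oracle=lambda form: form != "tale")
        hood = compute_neighborhood(db, params)
        # tali auto-included (>= autofreq); talk below minfreq; tale rejected
        assert hood["talo"] == 1

    def test_length_mismatch_never_neighbors(self):
        hood = compute_neighborhood(form_db(auto=20_000, autot=20_000))
        assert hood == {"auto": 0, "autot": 0}

    def test_default_oracle_accepts_mid_band(self):
        hood = compute_neighborhood(form_db(talo=20_000, tale=500))
        assert hood["talo"] == 1

    def test_params_validation(self):
        with pytest.raises(ValueError):
            NeighborhoodParams(autofreq=10, minfreq=100)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_matches_pairwise_brute_force(self, seed):
        db = db_from_spec(random_corpus_spec(seed, 120, max_form_len=5))
        params = NeighborhoodParams(
            autofreq=40, minfreq=5, validity_oracle=lambda f: hash(f) % 3 != 0
        )
        assert compute_neighborhood(db, params) == brute_force_hood(db, params)

    def test_symmetry_under_symmetric_inclusion(self):
        db = db_from_spec(random_corpus_spec(3, 150, max_form_len=4))
        params = NeighborhoodParams(autofreq=1, minfreq=0)  # everything included
        hood = compute_neighborhood(db, params)
        brute = brute_force_hood(db, params)
        assert hood == brute
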