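"""Parsing, encoding, hashing, decoding, scoring and ranking of SSWs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sswvision import phonology as ph
from sswvision.phonology import (CONSONANTS, DIM, SPECIALS1, SPECIALS2, VOWELS,
                                 GroupProbabilities, Mora, SSWForm)

from conftest import random_form, random_lexicon

# MD5 oracle bits computed independently (hash the 72-char '0'/'1' string,
# take the first 16 digest bits MSB-first) and frozen here.
HASH_ZERO_CORE = [0, 1, 1, 0, 0, 1, 1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
HASH_GOWA = [0, 1, 1, 0, 0, 0, 1, 0, 1, 0, 0, 0, 1, 1, 1, 1]
HASH_ZARA = [0, 1, 0, 0, 1, 0, 0, 0, 1, 0, 1, 1, 0, 1, 0, 0]


# ---------------------------------------------------------------------------
# Parsing


@pytest.mark.parametrize("text,c1,v1,c2,v2,rep", [
    ("gowa-gowa", "g", "o", "w", "a", True),
    ("zara-zara", "z", "a", "r", "a", True),
    ("fuwa-fuwa", "h", "u", "w", "a", True),   # Hepburn fu -> /h/ row
    ("puni", "p", "u", "n", "i", False),
    ("gowagowa", "g", "o", "w", "a", True),    # unhyphenated doubling
    ("shiku-shiku", "sy", "i", "k", "u", True),
    ("chiku-chiku", "ty", "i", "k", "u", True),
    ("tsuru-tsuru", "t", "u", "r", "u", True),
    ("jime-jime", "zy", "i", "m", "e", True),
    ("sasa", "s", "a", "s", "a", False),       # half-unit too short to reduplicate
])
def test_parse_examples(text, c1, v1, c2, v2, rep):
    form = ph.parse_ssw(text)
    assert form.mora1.consonant == c1
    assert form.mora1.vowel == v1
    assert form.mora2.consonant == c2
    assert form.mora2.vowel == v2
    assert form.repetition is rep


def test_parse_special_phonemes():
    f = ph.parse_ssw("shittori")
    assert f.mora1.specials == {"Q"}
    assert f.mora2.specials == {"Li"}
    f = ph.parse_ssw("zabun-zabun")
    assert f.mora2.specials == {"N"}
    f = ph.parse_ssw("buuwa")
    assert f.mora1.specials == {"R"} and f.mora1.vowel == "u"


@pytest.mark.parametrize("bad", ["", "   ", None])
def test_parse_empty_raises(bad):
    with pytest.raises(ph.EmptyInput):
        ph.parse_ssw(bad)


@pytest.mark.parametrize("bad", ["x1y2", "さらさら", "q", "sa", "gowa-zara", "kkk"])
def test_parse_unparseable_raises(bad):
    with pytest.raises(ph.UnparseableSSW):
        ph.parse_ssw(bad)


def test_canonicalize_merges_spelling_variants():
    assert ph.canonicalize("gowagowa") == ph.canonicalize("gowa-gowa") == "gowa-gowa"
    assert ph.canonicalize("huwa-huwa") == ph.canonicalize("fuwa-fuwa")


# ---------------------------------------------------------------------------
# Rendering


@pytest.mark.parametrize("form,expected", [
    (SSWForm(Mora("g", "o"), Mora("w", "a"), True), "gowa-gowa"),
    (SSWForm(Mora("s", "a"), Mora("r", "a"), True), "sara-sara"),
    (SSWForm(Mora("h", "u"), Mora("w", "a"), True), "fuwa-fuwa"),
    (SSWForm(Mora("t", "u"), Mora("t", "u"), False), "tsutsu"),
])
def test_render_examples(form, expected):
    assert ph.render_ssw(form) == expected


@settings(max_examples=300, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_parse_render_roundtrip_random_forms(seed):
    """parse(render(form)) recovers the form exactly, specials included."""
    form = random_form(np.random.default_rng(seed), special_rate=0.25)
    assert ph.parse_ssw(ph.render_ssw(form)) == form


# ---------------------------------------------------------------------------
# Encoding and hashing


def test_encode_gowa_gowa_bit_positions():
    v = ph.encode_ssw(ph.parse_ssw("gowa-gowa"))
    assert len(v) == DIM
    assert v[ph.V1.start + VOWELS.index("o")] == 1
    assert v[ph.C1.start + CONSONANTS.index("g")] == 1
    assert v[ph.V2.start + VOWELS.index("a")] == 1
    assert v[ph.C2.start + CONSONANTS.index("w")] == 1
    assert v[ph.S1].sum() == 0 and v[ph.S2].sum() == 0
    assert v[ph.R.start] == 1
    assert list(v[ph.H]) == HASH_GOWA


def test_encode_one_hot_groups_and_determinism():
    rng = np.random.default_rng(5)
    for form in random_lexicon(rng, 50):
        v = ph.encode_ssw(form)
        for g in (ph.V1, ph.C1, ph.V2, ph.C2):
            assert v[g].sum() == 1
        assert np.array_equal(v, ph.encode_ssw(form))
        assert np.array_equal(v[ph.H], ph.compute_hash_bits(v[:ph.CORE_DIM]))


def test_hash_bits_frozen_oracle_values():
    assert list(ph.compute_hash_bits([0] * 72)) == HASH_ZERO_CORE
    zara = ph.encode_ssw(ph.parse_ssw("zara-zara"))
    assert list(zara[ph.H]) == HASH_ZARA
    assert HASH_GOWA != HASH_ZARA  # computed independently per core


def test_hash_bits_wrong_length_raises():
    with pytest.raises(ph.WrongLength):
        ph.compute_hash_bits([0] * 71)


# ---------------------------------------------------------------------------
# Decoding


def test_decode_table3_is_gowa_gowa(table3_probs):
    assert ph.render_ssw(ph.decode_argmax(table3_probs)) == "gowa-gowa"


def test_decode_inverts_encoding():
    rng = np.random.default_rng(11)
    for form in random_lexicon(rng, 60, special_rate=0.3):
        v = ph.encode_ssw(form).astype(float)
        probs = GroupProbabilities(v[ph.V1], v[ph.C1], v[ph.S1], v[ph.V2],
                                   v[ph.C2], v[ph.S2], v[ph.R.start], v[ph.H])
        assert ph.decode_argmax(probs) == form


def test_decode_uniform_takes_first_inventory_elements():
    probs = GroupProbabilities(np.full(5, .2), np.full(27, 1 / 27), np.full(3, .5),
                               np.full(5, .2), np.full(27, 1 / 27), np.full(4, .5),
                               r=0.5)
    form = ph.decode_argmax(probs)
    assert form.mora1 == Mora("k", "a") and form.mora2 == Mora("k", "a")
    assert not form.repetition


def test_decode_invalid_probabilities_raise():
    bad = GroupProbabilities(np.full(5, .5), np.full(27, 1 / 27), np.full(3, .5),
                             np.full(5, .2), np.full(27, 1 / 27), np.full(4, .5),
                             r=0.5)
    with pytest.raises(ph.InvalidProbabilities):
        ph.decode_argmax(bad)


# ---------------------------------------------------------------------------
# Scoring


def bruteforce_cross_entropy(output, form):
    """Independent elementwise oracle: softmax CE + Bernoulli CE per bit."""
    t = ph.encode_ssw(form).astype(float)
    x = np.asarray(output, dtype=float)
    loss = 0.0
    for g in ph.SOFTMAX_GROUPS:
        p = np.exp(x[g]) / np.exp(x[g]).sum()
        loss += -np.log(p[t[g] == 1]).sum()
    for g in ph.SIGMOID_GROUPS:
        s = 1.0 / (1.0 + np.exp(-x[g]))
        loss += -(t[g] * np.log(s) + (1 - t[g]) * np.log(1 - s)).sum()
    return loss


def test_score_matches_bruteforce_oracle():
    rng = np.random.default_rng(3)
    for _ in range(100):
        out = rng.normal(scale=2.0, size=DIM)
        form = random_form(rng)
        assert ph.score_candidate(out, form) == pytest.approx(
            bruteforce_cross_entropy(out, form), abs=1e-9)


def test_score_perfect_prediction_approaches_zero():
    form = ph.parse_ssw("gowa-gowa")
    t = ph.encode_ssw(form).astype(float)
    out = 60.0 * (2 * t - 1)  # saturate every group toward the target
    assert ph.score_candidate(out, form) < 1e-6
    assert ph.score_candidate(out, ph.parse_ssw("puni")) > 1.0


def test_score_matrix_agrees_with_scalar_scores():
    rng = np.random.default_rng(9)
    forms = random_lexicon(rng, 20)
    outs = rng.normal(size=(4, DIM))
    targets = np.stack([ph.encode_ssw(f) for f in forms])
    M = ph.score_matrix(outs, targets)
    for i in range(4):
        for j in (0, 7, 19):
            assert M[i, j] == pytest.approx(ph.score_candidate(outs[i], forms[j]),
                                            abs=1e-9)


# ---------------------------------------------------------------------------
# Ranking


def test_rank_candidates_is_bruteforce_sort():
    rng = np.random.default_rng(21)
    lexicon = random_lexicon(rng, 300)
    out = rng.normal(size=DIM)
    expected = sorted(lexicon, key=lambda f: ph.score_candidate(out, f))
    got = ph.rank_candidates(out, lexicon, k=len(lexicon))
    assert [ph.render_ssw(f) for f, _ in got[:25]] == \
        [ph.render_ssw(f) for f in expected[:25]]
    assert got[0][0] == expected[0]  # k=1 argmin case


def test_rank_empty_lexicon_raises():
    with pytest.raises(ph.EmptyLexicon):
        ph.rank_candidates(np.zeros(DIM), [])


def test_hash_mismatch_strictly_increases_loss():
    """With identical per-slot fit, a word whose hash block disagrees with the
    output's hash preference ranks strictly below the matching word."""
    gowa = ph.parse_ssw("gowa-gowa")
    zowa = ph.parse_ssw("zowa-zowa")  # same structure: no specials, repeated
    out = np.zeros(DIM)  # uniform over every slot: identical non-hash fit
    out[ph.H] = 10.0 * (2 * ph.encode_ssw(gowa)[ph.H].astype(float) - 1)
    assert ph.score_candidate(out, gowa) < ph.score_candidate(out, zowa)
    ranked = ph.rank_candidates(out, [zowa, gowa], k=2)
    assert ranked[0][0] == gowa


# ---------------------------------------------------------------------------
# Enumeration


def test_enumerate_depth1_is_argmax_decode(table3_probs):
    assert ph.enumerate_by_rank(table3_probs, 1) == ["gowa-gowa"]


def test_enumerate_depth4_contains_published_neighbours(table3_probs):
    words = ph.enumerate_by_rank(table3_probs, 4)
    assert words[0] == "gowa-gowa"
    assert "zara-zara" in words


def test_enumerate_probability_mass_conserved(table3_probs):
    pairs = ph.enumerate_by_rank(table3_probs, 2, return_probs=True)
    total = sum(p for _, p in pairs)
    assert 0 < total <= 1.0 + 1e-9
    assert [p for _, p in pairs] == sorted((p for _, p in pairs), reverse=True)
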