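"""Phonological encoding, decoding and scoring of Japanese sound-symbolic words.

A Japanese sound-symbolic word (SSW, onomatopoeia) such as ``zara-zara`` or
``fuwa-fuwa`` conveys texture sensation through its phonemes: voiced obstruents
evoke roughness, voiceless ones smoothness, the back vowel /u/ soft and pleasant
feelings, and so on.  This module represents an SSW by the first two morae of
its repetition unit and encodes that structure as an 88-dimensional binary
vector laid out as

    v1 (5)  one-hot vowel of mora 1            /a/ /i/ /u/ /e/ /o/
    c1 (27) one-hot consonant of mora 1        25 consonants, palatalized rows,
                                               or explicit absence
    s1 (3)  multi-hot special phonemes         /N/ /Q/ /R/
    v2 (5)  one-hot vowel of mora 2
    c2 (27) one-hot consonant of mora 2
    s2 (4)  multi-hot special phonemes         /N/ /Q/ /R/ /Li/
    r  (1)  repetition flag
    h  (16) MD5 hash of the 72 bits above      correlation code

The hash block lets a model whose per-slot outputs are otherwise independent
penalize implausible phoneme combinations: two words that fit the per-slot
probabilities equally well are separated by their hash bits.

Cross-entropy scoring treats v1, c1, v2, c2 as softmax groups and s1, s2, r, h
as independent sigmoid bits, mirroring how the prediction model is trained.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp

__all__ = [
    "VOWELS", "CONSONANTS", "ABSENCE", "SPECIALS1", "SPECIALS2",
    "V1", "C1", "S1", "V2", "C2", "S2", "R", "H", "CORE_DIM", "DIM",
    "SOFTMAX_GROUPS", "SIGMOID_GROUPS",
    "Mora", "SSWForm", "GroupProbabilities",
    "UnparseableSSW", "EmptyInput", "InvalidProbabilities", "WrongLength",
    "EmptyLexicon",
    "parse_ssw", "render_ssw", "canonicalize", "encode_ssw", "compute_hash_bits",
    "decode_argmax", "score_candidate", "score_lexicon", "rank_candidates",
    "enumerate_by_rank",
]

# ---------------------------------------------------------------------------
# Inventory (canonical ordering; all one-hot indices derive from it)

VOWELS = ("a", "i", "u", "e", "o")
ABSENCE = ""
CONSONANTS = (
    "k", "ky", "g", "gy", "s", "sy", "z", "zy", "t", "ty",
    "d", "dy", "n", "ny", "h", "hy", "b", "by", "p", "py",
    "m", "my", "y", "r", "ry", "w", ABSENCE,
)
SPECIALS1 = ("N", "Q", "R")
SPECIALS2 = ("N", "Q", "R", "Li")

V1 = slice(0, 5)
C1 = slice(5, 32)
S1 = slice(32, 35)
V2 = slice(35, 40)
C2 = slice(40, 67)
S2 = slice(67, 71)
R = slice(71, 72)
H = slice(72, 88)
CORE_DIM = 72
DIM = 88
SOFTMAX_GROUPS = (V1, C1, V2, C2)
SIGMOID_GROUPS = (S1, S2, R, H)

_VIDX = {v: i for i, v in enumerate(VOWELS)}
_CIDX = {c: i for i, c in enumerate(CONSONANTS)}


class UnparseableSSW(ValueError):
    """Input cannot be analysed as a two-mora sound-symbolic word."""


class EmptyInput(UnparseableSSW):
    """Empty or whitespace-only input."""


class InvalidProbabilities(ValueError):
    """Probability vectors violate the softmax/sigmoid layout invariants."""


class WrongLength(ValueError):
    """Bit sequence has an unexpected length."""


class EmptyLexicon(ValueError):
    """Candidate ranking requires a non-empty lexicon."""


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class Mora:
    """One mora: a consonant slot (possibly absent), a vowel, trailing specials."""

    consonant: str
    vowel: str
    specials: frozenset = frozenset()

    def __post_init__(self):
        if self.consonant not in _CIDX:
            raise UnparseableSSW(f"unknown consonant {self.consonant!r}")
        if self.vowel not in _VIDX:
            raise UnparseableSSW(f"unknown vowel {self.vowel!r}")
        object.__setattr__(self, "specials", frozenset(self.specials))


@dataclass(frozen=True)
class SSWForm:
    """Parsed two-mora structure of an SSW repetition unit.

    ``surface`` keeps the romanized source text for reference and is excluded
    from equality; two forms are equal iff their phonological content is.
    """

    mora1: Mora
    mora2: Mora
    repetition: bool
    surface: str = field(default="", compare=False)

    def __post_init__(self):
        if not self.mora1.specials <= set(SPECIALS1):
            raise UnparseableSSW(
                f"mora-1 specials must be within {SPECIALS1}: {set(self.mora1.specials)}")
        if not self.mora2.specials <= set(SPECIALS2):
            raise UnparseableSSW(
                f"mora-2 specials must be within {SPECIALS2}: {set(self.mora2.specials)}")

    def render(self) -> str:
        return render_ssw(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


@dataclass
class GroupProbabilities:
    """Normalized model output mirroring the 88-dim layout.

    Softmax groups (v1, c1, v2, c2) must each sum to 1; sigmoid entries
    (s1, s2, r, h) each lie in [0, 1].
    """

    v1: np.ndarray
    c1: np.ndarray
    s1: np.ndarray
    v2: np.ndarray
    c2: np.ndarray
    s2: np.ndarray
    r: float
    h: np.ndarray = None

    def __post_init__(self):
        self.v1 = np.asarray(self.v1, dtype=float)
        self.c1 = np.asarray(self.c1, dtype=float)
        self.s1 = np.asarray(self.s1, dtype=float)
        self.v2 = np.asarray(self.v2, dtype=float)
        self.c2 = np.asarray(self.c2, dtype=float)
        self.s2 = np.asarray(self.s2, dtype=float)
        self.r = float(self.r)
        self.h = np.full(16, 0.5) if self.h is None else np.asarray(self.h, dtype=float)

    @classmethod
    def from_raw(cls, output: np.ndarray) -> "GroupProbabilities":
        """Normalize a raw 88-dim model output (softmax / sigmoid per group)."""
        x = np.asarray(output, dtype=float).reshape(-1)
        if x.size != DIM:
            raise WrongLength(f"raw output must have {DIM} entries, got {x.size}")

        def smax(v):
            e = np.exp(v - v.max())
            return e / e.sum()

        sig = expit
        return cls(
            v1=smax(x[V1]), c1=smax(x[C1]), s1=sig(x[S1]),
            v2=smax(x[V2]), c2=smax(x[C2]), s2=sig(x[S2]),
            r=float(sig(x[R])[0]), h=sig(x[H]),
        )

    def validate(self, atol: float = 1e-6) -> None:
        for name, vec, n in (("v1", self.v1, 5), ("c1", self.c1, 27),
                             ("v2", self.v2, 5), ("c2", self.c2, 27)):
            if vec.size != n:
                raise InvalidProbabilities(f"{name} must have {n} entries")
            if not np.isclose(vec.sum(), 1.0, atol=atol) or (vec < -atol).any():
                raise InvalidProbabilities(f"{name} is not a probability simplex point")
        for name, vec, n in (("s1", self.s1, 3), ("s2", self.s2, 4), ("h", self.h, 16)):
            if vec.size != n:
                raise InvalidProbabilities(f"{name} must have {n} entries")
            if ((vec < -atol) | (vec > 1 + atol)).any():
                raise InvalidProbabilities(f"{name} entries must lie in [0, 1]")
        if not 0 - atol <= self.r <= 1 + atol:
            raise InvalidProbabilities("r must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Parsing (Hepburn-style romanization -> SSWForm)

_VOWELSET = set(VOWELS)
_PALATALS = {"ky", "gy", "sy", "zy", "ty", "dy", "ny", "hy", "by", "py", "my", "ry"}
_HEPBURN_DIGRAPHS = {"sh": "sy", "ch": "ty", "ts": "t"}
_SINGLES = set("kgsztdnhbpmyrw")


def _parse_unit(unit: str, text: str) -> list:
    """Split a repetition unit into morae ``[consonant, vowel, specials-set]``."""
    morae: list = []
    i, n = 0, len(unit)
    prev_was_vowel = False
    sep = False

    def last():
        if not morae:
            raise UnparseableSSW(f"{text!r}: special phoneme with no preceding mora")
        return morae[-1]

    while i < n:
        ch = unit[i]
        if ch == "'":  # explicit mora boundary (e.g. zan'ya, sa'a)
            sep = True
            prev_was_vowel = False
            i += 1
            continue
        if ch == "q":  # canonical marker for a geminate with nothing to double
            last()[2].add("Q")
            prev_was_vowel = False
            i += 1
            continue
        if ch in _VOWELSET:
            if morae and morae[-1][1] == ch and prev_was_vowel and not sep:
                last()[2].add("R")  # long vowel: consume the run
                while i < n and unit[i] == ch:
                    i += 1
            else:
                morae.append([ABSENCE, ch, set()])
                i += 1
            prev_was_vowel = True
            sep = False
            continue
        sep = False
        prev_was_vowel = False
        # moraic nasal: n not followed by a vowel or y
        if ch == "n" and (i + 1 >= n or (unit[i + 1] not in _VOWELSET and unit[i + 1] != "y")):
            last()[2].add("N")
            i += 1
            continue
        # Hepburn geminate of ch- is written tch (matcha)
        if ch == "t" and unit[i + 1:i + 3] == "ch":
            last()[2].add("Q")
            i += 1
            continue
        # doubled consonant letter = geminate on the previous mora
        if i + 1 < n and unit[i + 1] == ch and ch not in _VOWELSET and ch != "n":
            last()[2].add("Q")
            i += 1
            continue
        # onset
        two = unit[i:i + 2]
        if two in _HEPBURN_DIGRAPHS:
            cons = _HEPBURN_DIGRAPHS[two]
            i += 2
        elif two in _PALATALS:
            cons = two
            i += 2
        elif ch == "j":
            cons = "zy"
            i += 1
        elif ch == "f":
            cons = "h"
            i += 1
        elif ch in _SINGLES:
            cons = ch
            i += 1
        else:
            raise UnparseableSSW(f"{text!r}: symbol {ch!r} outside the phoneme inventory")
        if i >= n or unit[i] not in _VOWELSET:
            raise UnparseableSSW(f"{text!r}: consonant {cons!r} is not followed by a vowel")
        morae.append([cons, unit[i], set()])
        i += 1
        prev_was_vowel = True
    return morae


def _form_from_morae(morae: list, repetition: bool, text: str) -> SSWForm:
    if len(morae) < 2:
        raise UnparseableSSW(
            f"{text!r}: a repetition unit needs at least two morae")
    li = False
    # word-final plain "ri" in a three-mora unit is the /Li/ ending (shitto-ri)
    if len(morae) == 3 and morae[2][0] == "r" and morae[2][1] == "i" and not morae[2][2]:
        li = True
    m1 = Mora(morae[0][0], morae[0][1], frozenset(morae[0][2]))
    s2 = set(morae[1][2]) | ({"Li"} if li else set())
    m2 = Mora(morae[1][0], morae[1][1], frozenset(s2))
    return SSWForm(m1, m2, repetition, surface=text)


def parse_ssw(text: str) -> SSWForm:
    """Parse a romanized SSW into its two-mora repetition-unit structure.

    Accepts Hepburn spellings (``fu``, ``shi``, ``chi``, ``tsu``, ``ji`` and
    the palatalized digraphs) as well as the phonemic spellings used by the
    canonical renderer.  Repetition is marked by a hyphen (``gowa-gowa``) or by
    exact doubling (``gowagowa``).  Units longer than two morae are truncated
    to the first two, except that a final plain ``ri`` third mora is kept as
    the /Li/ special phoneme.
    """
    if text is None or not str(text).strip():
        raise EmptyInput("empty SSW input")
    s = str(text).strip().lower()
    if not all(c.isascii() and (c.isalpha() or c in "-'") for c in s):
        raise UnparseableSSW(f"{text!r}: non-romanized characters")
    if "-" in s:
        parts = s.split("-")
        if len(parts) == 2 and parts[0] and parts[0] == parts[1]:
            return _form_from_morae(_parse_unit(parts[0], text), True, text)
        raise UnparseableSSW(f"{text!r}: hyphen must separate two identical units")
    n = len(s)
    if n % 2 == 0 and s[: n // 2] == s[n // 2:]:
        try:
            return _form_from_morae(_parse_unit(s[: n // 2], text), True, text)
        except UnparseableSSW:
            pass  # e.g. "sasa": half-unit too short; fall through to plain parse
    return _form_from_morae(_parse_unit(s, text), False, text)


# ---------------------------------------------------------------------------
# Rendering (SSWForm -> canonical Hepburn romanization)


def _render_base(mora: Mora) -> str:
    c, v = mora.consonant, mora.vowel
    if c == ABSENCE:
        return v
    if c == "sy":
        return "shi" if v == "i" else "sh" + v
    if c == "ty":
        return "chi" if v == "i" else "ch" + v
    if c == "zy":
        return "ji" if v == "i" else "j" + v
    if c == "t" and v == "u":
        return "tsu"
    if c == "h" and v == "u":
        return "fu"
    return c + v


def render_ssw(form: SSWForm) -> str:
    """Canonical romanization; the repetition unit is hyphen-doubled iff r=1.

    Conventions: /R/ doubles the vowel letter, /N/ is ``n`` (with ``'`` before
    a following vowel or ``y``), /Q/ doubles the next onset letter (``tch``
    before ``ch``) or is written ``q`` when nothing follows, /Li/ appends
    ``ri``.  An apostrophe separates a vowel-initial second mora from an
    identical preceding vowel so that parsing is unambiguous.
    """
    m1, m2 = form.mora1, form.mora2
    part1 = _render_base(m1)
    if "R" in m1.specials:
        part1 += m1.vowel
    if "N" in m1.specials:
        part1 += "n"
    base2 = _render_base(m2)
    mid = ""  # surface realization of m1's geminate, if any
    if "Q" in m1.specials:
        if m2.consonant == ABSENCE or base2[0] == "n":
            mid = "q"
        elif base2.startswith("ch"):
            mid = "t"
        else:
            mid = base2[0]
    part2 = base2
    if "R" in m2.specials:
        part2 += m2.vowel
    if "Q" in m2.specials:
        part2 += "q"
    if "N" in m2.specials:
        part2 += "n"
    if "Li" in m2.specials:
        part2 += "ri"
    head = part1
    nxt = (mid + base2)[0]
    if part1.endswith("n") and (nxt in _VOWELSET or nxt == "y"):
        head += "'"  # keep the moraic nasal from merging into the next onset
    head += mid
    if not mid and m2.consonant == ABSENCE and head[-1] == m2.vowel:
        head += "'"  # keep a vowel-initial mora 2 from reading as a long vowel
    unit = head + part2
    return unit + "-" + unit if form.repetition else unit


def canonicalize(text: str) -> str:
    """Canonical romanization of an SSW token (parse then render)."""
    return render_ssw(parse_ssw(text))


# ---------------------------------------------------------------------------
# Binary encoding


def compute_hash_bits(core) -> np.ndarray:
    """16 correlation-hash bits of the 72 non-hash bits.

    The core bits are rendered as a '0'/'1' character string in layout order,
    MD5-hashed, and the first 16 digest bits are taken most-significant-bit
    first.  Deterministic across runs and platforms.
    """
    core = np.asarray(core).reshape(-1)
    if core.size != CORE_DIM:
        raise WrongLength(f"core must have {CORE_DIM} bits, got {core.size}")
    s = "".join("1" if b else "0" for b in core).encode("ascii")
    digest = hashlib.md5(s).digest()
    bits = [(digest[byte] >> (7 - bit)) & 1 for byte in range(2) for bit in range(8)]
    return np.array(bits, dtype=np.int8)


def encode_ssw(form: SSWForm) -> np.ndarray:
    """Encode a parsed SSW as the 88-dim binary vector (hash block included)."""
    v = np.zeros(DIM, dtype=np.int8)
    v[V1.start + _VIDX[form.mora1.vowel]] = 1
    v[C1.start + _CIDX[form.mora1.consonant]] = 1
    for sp in form.mora1.specials:
        v[S1.start + SPECIALS1.index(sp)] = 1
    v[V2.start + _VIDX[form.mora2.vowel]] = 1
    v[C2.start + _CIDX[form.mora2.consonant]] = 1
    for sp in form.mora2.specials:
        v[S2.start + SPECIALS2.index(sp)] = 1
    if form.repetition:
        v[R.start] = 1
    v[H] = compute_hash_bits(v[:CORE_DIM])
    return v


def decode_argmax(probs: GroupProbabilities) -> SSWForm:
    """Combine the most probable element of every slot into one SSW.

    Softmax groups take their argmax (ties resolved toward the earlier
    inventory position); each sigmoid element is included iff its probability
    exceeds 0.5.
    """
    probs.validate()
    m1 = Mora(
        CONSONANTS[int(np.argmax(probs.c1))],
        VOWELS[int(np.argmax(probs.v1))],
        frozenset(sp for i, sp in enumerate(SPECIALS1) if probs.s1[i] > 0.5),
    )
    m2 = Mora(
        CONSONANTS[int(np.argmax(probs.c2))],
        VOWELS[int(np.argmax(probs.v2))],
        frozenset(sp for i, sp in enumerate(SPECIALS2) if probs.s2[i] > 0.5),
    )
    return SSWForm(m1, m2, probs.r > 0.5)


# ---------------------------------------------------------------------------
# Cross-entropy scoring and lexicon ranking


def _softplus(x):
    # log(1 + e^x), stable
    return np.logaddexp(0.0, x)


def score_candidate(output, form: SSWForm) -> float:
    """Cross-entropy loss between a raw 88-dim model output and an SSW.

    Softmax cross-entropy over v1, c1, v2, c2 plus sigmoid (Bernoulli)
    cross-entropy over every s1, s2, r and h bit.  This is the quantity the
    model is trained on and the one used to rank lexicon candidates.
    """
    x = np.asarray(output, dtype=float).reshape(-1)
    if x.size != DIM:
        raise WrongLength(f"raw output must have {DIM} entries, got {x.size}")
    t = encode_ssw(form).astype(float)
    loss = 0.0
    for g in SOFTMAX_GROUPS:
        loss += logsumexp(x[g]) - float(x[g] @ t[g])
    for g in SIGMOID_GROUPS:
        loss += float(t[g] @ _softplus(-x[g]) + (1.0 - t[g]) @ _softplus(x[g]))
    return float(loss)


def score_lexicon(output, forms) -> np.ndarray:
    """Vectorized :func:`score_candidate` over a list of forms."""
    x = np.asarray(output, dtype=float).reshape(-1)
    if x.size != DIM:
        raise WrongLength(f"raw output must have {DIM} entries, got {x.size}")
    T = np.stack([encode_ssw(f) for f in forms]).astype(float)
    losses = np.zeros(len(forms))
    for g in SOFTMAX_GROUPS:
        losses += logsumexp(x[g]) - T[:, g] @ x[g]
    for g in SIGMOID_GROUPS:
        losses += T[:, g] @ _softplus(-x[g]) + (1.0 - T[:, g]) @ _softplus(x[g])
    return losses


def score_matrix(outputs, targets) -> np.ndarray:
    """Cross-entropy losses of every output against every encoded target.

    ``outputs`` is (n, 88) raw model outputs; ``targets`` is (L, 88) binary
    encodings (rows of :func:`encode_ssw`).  Returns an (n, L) loss matrix;
    row i column j is ``score_candidate(outputs[i], word_j)``.
    """
    X = np.atleast_2d(np.asarray(outputs, dtype=float))
    T = np.atleast_2d(np.asarray(targets, dtype=float))
    if X.shape[1] != DIM or T.shape[1] != DIM:
        raise WrongLength("outputs and targets must have 88 columns")
    losses = np.zeros((X.shape[0], T.shape[0]))
    neg = _softplus(-X)
    pos = _softplus(X)
    for g in SOFTMAX_GROUPS:
        lse = logsumexp(X[:, g], axis=1)
        losses += lse[:, None] - X[:, g] @ T[:, g].T
    for g in SIGMOID_GROUPS:
        losses += neg[:, g] @ T[:, g].T + pos[:, g] @ (1.0 - T[:, g]).T
    return losses


def rank_candidates(output, lexicon, k: int = 2, counts=None):
    """Top-``k`` lexicon words by ascending cross-entropy against an output.

    ``counts`` optionally maps canonical word strings to corpus frequencies;
    ties in loss are broken by higher frequency, then lexicographically.
    Returns ``[(SSWForm, loss), ...]``.
    """
    lexicon = list(lexicon)
    if not lexicon:
        raise EmptyLexicon("rank_candidates requires a non-empty lexicon")
    losses = score_lexicon(output, lexicon)
    counts = counts or {}

    def key(i):
        w = render_ssw(lexicon[i])
        return (losses[i], -counts.get(w, 0), w)

    order = sorted(range(len(lexicon)), key=key)
    return [(lexicon[i], float(losses[i])) for i in order[:k]]


def enumerate_by_rank(probs: GroupProbabilities, depth: int = 1,
                      return_probs: bool = False):
    """Enumerate candidate SSW strings from the per-slot probability tables.

    Each softmax slot is restricted to its ``depth`` most probable elements
    (and each binary sigmoid slot to its more probable state when depth is 1,
    both states otherwise); every combination is then listed in descending
    product-of-probabilities order.  ``depth=1`` reproduces the argmax decode.
    Returns the distinct rendered strings in that order, or ``(string,
    product-probability)`` pairs when ``return_probs`` is set.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    probs.validate()

    def top(vec, items):
        order = np.argsort(-np.asarray(vec), kind="stable")[:depth]
        return [(items[i], float(vec[i])) for i in order]

    def binary(p, item):
        states = sorted(
            [(frozenset([item]) if item else True, p),
             (frozenset() if item else False, 1.0 - p)],
            key=lambda s: -s[1],
        )
        return states[: (1 if depth == 1 else 2)]

    v1 = top(probs.v1, VOWELS)
    c1 = top(probs.c1, CONSONANTS)
    v2 = top(probs.v2, VOWELS)
    c2 = top(probs.c2, CONSONANTS)
    s1_states = [binary(float(probs.s1[i]), sp) for i, sp in enumerate(SPECIALS1)]
    s2_states = [binary(float(probs.s2[i]), sp) for i, sp in enumerate(SPECIALS2)]
    r_states = binary(probs.r, None)

    results = []
    for combo in itertools.product(v1, c1, v2, c2, *s1_states, *s2_states, r_states):
        p = 1.0
        for _, q in combo:
            p *= q
        (vow1, _), (con1, _), (vow2, _), (con2, _) = combo[:4]
        sp1 = frozenset().union(*(s for s, _ in combo[4:7]))
        sp2 = frozenset().union(*(s for s, _ in combo[7:11]))
        rep = combo[11][0]
        try:
            form = SSWForm(Mora(con1, vow1, sp1), Mora(con2, vow2, sp2), rep)
        except UnparseableSSW:  # pragma: no cover - inventories make this unreachable
            continue
        results.append((p, render_ssw(form)))
    results.sort(key=lambda t: (-t[0], t[1]))
    seen, out = set(), []
    for p, word in results:
        if word not in seen:
            seen.add(word)
            out.append((word, p) if return_probs else word)
    return out
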