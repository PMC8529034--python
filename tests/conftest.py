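import numpy as np
import pytest

from sswvision import phonology
from sswvision.phonology import CONSONANTS, GroupProbabilities


def _fill(named, size, rest, index):
    """Probability vector with named entries and the remainder spread evenly."""
    v = np.full(size, rest)
    for key, p in named.items():
        v[index(key)] = p
    return v


@pytest.fixture
def table3_probs() -> GroupProbabilities:
    """The published worked example of a normalized output array.

    Only the four most probable elements per slot are printed; the remaining
    probability mass is spread uniformly over the unlisted elements, which
    leaves every argmax and every top-4 ranking unchanged.
    """
    cidx = CONSONANTS.index
    vidx = "aiueo".index
    v1 = _fill({"o": 0.56, "a": 0.29, "u": 0.08, "i": 0.05}, 5, 0.02, vidx)
    c1 = _fill({"g": 0.34, "z": 0.22, "m": 0.15, "b": 0.10}, 27, 0.19 / 23, cidx)
    s1 = np.array([0.02, 0.01, 0.01])  # N, Q, R
    v2 = _fill({"a": 0.75, "o": 0.11, "u": 0.07, "i": 0.05}, 5, 0.02, vidx)
    c2 = _fill({"w": 0.38, "r": 0.19, "s": 0.13, "k": 0.09}, 27, 0.21 / 23, cidx)
    s2 = np.array([0.01, 0.02, 0.01, 0.01])  # N, Q, R, Li
    return GroupProbabilities(v1, c1, s1, v2, c2, s2, r=0.96)


def random_form(rng, special_rate: float = 0.15) -> phonology.SSWForm:
    """One random well-formed SSW."""
    m1 = phonology.Mora(
        CONSONANTS[rng.integers(len(CONSONANTS))],
        phonology.VOWELS[rng.integers(5)],
        frozenset(s for s in phonology.SPECIALS1 if rng.random() < special_rate),
    )
    m2 = phonology.Mora(
        CONSONANTS[rng.integers(len(CONSONANTS))],
        phonology.VOWELS[rng.integers(5)],
        frozenset(s for s in phonology.SPECIALS2 if rng.random() < special_rate),
    )
    return phonology.SSWForm(m1, m2, bool(rng.random() < 0.8))


def random_lexicon(rng, n: int, special_rate: float = 0.15):
    """n distinct random forms."""
    seen, forms = set(), []
    while len(forms) < n:
        f = random_form(rng, special_rate)
        w = phonology.render_ssw(f)
        if w not in seen:
            seen.add(w)
            forms.append(f)
    return forms
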