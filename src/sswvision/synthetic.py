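"""Procedural texture corpus with sound-symbolically consistent annotations.

The human-annotated texture corpus this system was designed for is not
redistributable, so this module generates a stand-in: procedural texture
images controlled by latent perceptual parameters (roughness, glossiness,
softness, wetness, granularity), and simulated annotators whose phoneme
choices follow the documented sound-symbolic associations — voiced
consonants for rough surfaces, voiceless for smooth ones, the back vowel /u/
for soft pleasant textures, /o/ and /a/ for rough/hard/dry ones, bilabial
plosives and /n/ for soft, sticky and wet feelings, /k/ and the /t/-row for
hard, slippery and dry ones.  Because the generator plants these
associations, parameter-recovery tests can verify that the full
train-predict-evaluate loop picks them back up.

Textures are spectrally synthesized noise: roughness raises the
high-frequency amplitude, granularity sets the noise scale, glossiness adds
specular-like bright spots, softness blurs, wetness darkens.  Everything is
deterministic given the seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from . import dataset, phonology
from .dataset import AnnotationRecord
from .phonology import ABSENCE, CONSONANTS, VOWELS, SPECIALS1, SPECIALS2, Mora, SSWForm

__all__ = [
    "TextureParams", "AssociationRules", "SyntheticCorpus",
    "gen_texture", "simulate_annotations", "gen_corpus",
]

VOICED = {"g", "gy", "z", "zy", "d", "dy", "b", "by"}
VOICELESS = {"k", "ky", "s", "sy", "t", "ty", "h", "hy", "p", "py"}
_SOFT_WET_CONS = {"p", "b", "n"}
_HARD_DRY_CONS = {"k", "t", "ty"}
_PALATALS = {c for c in CONSONANTS if len(c) == 2 and c.endswith("y")}
# resting vowel preferences of texture vocabulary (e is rare, a/o/u common)
_VOWEL_BASE = {"a": 0.6, "i": 0.0, "u": 0.4, "e": -1.2, "o": 0.4}


@dataclass(frozen=True)
class TextureParams:
    """Latent perceptual parameters in [0, 1] driving image and annotations."""

    roughness: float = 0.5
    glossiness: float = 0.5
    softness: float = 0.5
    wetness: float = 0.5
    granularity: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("roughness", "glossiness", "softness", "wetness", "granularity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class AssociationRules:
    """Log-weights linking texture dimensions to phoneme choices.

    ``strength`` scales every association; at 0 annotators answer uniformly
    at random and no signal is planted.
    """

    strength: float = 6.0
    special_base: float = -4.5      # rare special phonemes
    li_base: float = -5.5
    repetition_base: float = 2.5    # most texture SSWs reduplicate
    absence_base: float = -3.0      # vowel-initial morae are uncommon
    palatal_base: float = -2.5      # palatalized rows are rare in texture words

    def consonant_logits(self, p: TextureParams) -> np.ndarray:
        w = self.strength
        rough = p.roughness - 0.5
        soft_wet = (p.softness + p.wetness) / 2.0 - 0.5
        hard_dry = ((1 - p.softness) + (1 - p.wetness) + p.glossiness) / 3.0 - 0.5
        logits = np.zeros(len(CONSONANTS))
        for i, c in enumerate(CONSONANTS):
            if c in _PALATALS:
                logits[i] += self.palatal_base
            if c in VOICED:
                logits[i] += w * rough
            elif c in VOICELESS:
                logits[i] -= w * rough
            if c in _SOFT_WET_CONS:
                logits[i] += w * soft_wet
            if c in _HARD_DRY_CONS:
                logits[i] += w * hard_dry
            if c == ABSENCE:
                logits[i] += self.absence_base
        return logits

    def vowel_logits(self, p: TextureParams) -> np.ndarray:
        w = self.strength
        rough_hard_dry = (p.roughness + (1 - p.softness) + (1 - p.wetness)) / 3.0 - 0.5
        negative = (p.roughness + (1 - p.glossiness)) / 2.0 - 0.5
        logits = np.array([_VOWEL_BASE[v] for v in VOWELS])
        logits[VOWELS.index("u")] += w * (p.softness - 0.5)
        logits[VOWELS.index("i")] += 0.5 * w * negative
        logits[VOWELS.index("e")] += 0.5 * w * negative
        logits[VOWELS.index("o")] += w * rough_hard_dry
        logits[VOWELS.index("a")] += w * rough_hard_dry
        return logits

    def special_logits(self, p: TextureParams):
        s1 = np.full(len(SPECIALS1), self.special_base)
        s2 = np.full(len(SPECIALS2), self.special_base)
        s2[SPECIALS2.index("Li")] = self.li_base
        # long vowels for soft fluffy textures, geminates for hard ones
        s1[SPECIALS1.index("R")] += p.softness - 0.5
        s1[SPECIALS1.index("Q")] += 0.5 - p.softness
        s2[SPECIALS2.index("R")] += p.softness - 0.5
        s2[SPECIALS2.index("Q")] += 0.5 - p.softness
        return s1, s2

    def repetition_logit(self, p: TextureParams) -> float:
        return self.repetition_base


# ---------------------------------------------------------------------------
# Texture synthesis


def _spectral_noise(rng, size, beta):
    """Zero-mean unit-variance noise with a 1/f^beta power spectrum."""
    white = rng.standard_normal((size, size))
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0
    spectrum = np.fft.fft2(white) * f ** (-beta / 2.0)
    spectrum[0, 0] = 0.0
    field = np.fft.ifft2(spectrum).real
    return (field - field.mean()) / (field.std() + 1e-12)


def gen_texture(params: TextureParams, size: int = 150) -> np.ndarray:
    """Render one RGB texture (uint8, size x size x 3), deterministic per seed."""
    rng = np.random.default_rng(params.seed)
    color = rng.uniform(0.35, 0.75, 3)
    # rough surfaces: flat spectrum (lots of high-frequency relief)
    beta = 2.6 - 2.0 * params.roughness
    relief = _spectral_noise(rng, size, beta)
    # granularity sets the feature scale of the relief
    sigma = 0.4 + 3.0 * (1.0 - params.granularity)
    relief = gaussian_filter(relief, sigma)
    relief /= relief.std() + 1e-12
    amplitude = 0.06 + 0.40 * params.roughness
    img = color[None, None, :] * (1.0 + amplitude * relief[..., None])
    # glossiness: sparse specular-like highlights
    n_spots = int(round(params.glossiness * 25))
    if n_spots:
        yy, xx = np.mgrid[0:size, 0:size]
        spots = np.zeros((size, size))
        for _ in range(n_spots):
            cy, cx = rng.uniform(0, size, 2)
            rad = rng.uniform(2.0, 6.0)
            spots += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * rad ** 2))
        img += (0.5 * params.glossiness) * np.clip(spots, 0, 1.5)[..., None]
    # softness smooths everything
    if params.softness > 0:
        img = gaussian_filter(img, (2.0 * params.softness, 2.0 * params.softness, 0))
    # wetness darkens and cools the surface
    img *= 1.0 - 0.30 * params.wetness
    img[..., 2] *= 1.0 + 0.15 * params.wetness
    return (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)


# ---------------------------------------------------------------------------
# Annotator simulation


def _sample_form(rules: AssociationRules, params: TextureParams, rng) -> SSWForm:
    """Sample one SSW with every slot drawn independently from its rule."""

    def softmax_draw(logits):
        e = np.exp(logits - logits.max())
        return int(rng.choice(len(logits), p=e / e.sum()))

    cons_logits = rules.consonant_logits(params)
    vow_logits = rules.vowel_logits(params)
    s1_logits, s2_logits = rules.special_logits(params)
    sig = lambda x: 1.0 / (1.0 + np.exp(-x))
    m1 = Mora(CONSONANTS[softmax_draw(cons_logits)], VOWELS[softmax_draw(vow_logits)],
              frozenset(sp for sp, lg in zip(SPECIALS1, s1_logits)
                        if rng.random() < sig(lg)))
    m2 = Mora(CONSONANTS[softmax_draw(cons_logits)], VOWELS[softmax_draw(vow_logits)],
              frozenset(sp for sp, lg in zip(SPECIALS2, s2_logits)
                        if rng.random() < sig(lg)))
    rep = rng.random() < sig(rules.repetition_logit(params))
    return SSWForm(m1, m2, rep)


def simulate_annotations(params: TextureParams, rules: AssociationRules = None,
                         annotators: int = 10, seed=None, image_id: str = "img0"):
    """Simulate each annotator answering 1-6 SSW tokens for one texture."""
    rules = rules or AssociationRules()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    records = []
    for a in range(annotators):
        n_tokens = int(rng.integers(1, 7))
        tokens = tuple(phonology.render_ssw(_sample_form(rules, params, rng))
                       for _ in range(n_tokens))
        records.append(AnnotationRecord(image_id, f"p{a:02d}", tokens))
    return records


# ---------------------------------------------------------------------------
# Whole corpora


@dataclass
class SyntheticCorpus:
    """Images, annotations and the ground-truth parameters that made them."""

    images: dict
    annotations: list
    params: dict
    rules: AssociationRules = field(default_factory=AssociationRules)

    @property
    def image_ids(self):
        return list(self.images)

    def lexicon(self):
        return dataset.build_lexicon(self.annotations)

    def answered_sets(self):
        """image id -> set of canonical answered words (correctness reference)."""
        out = {i: set() for i in self.images}
        for rec in self.annotations:
            out[rec.image_id].update(phonology.canonicalize(t) for t in rec.tokens)
        return out

    def pairs(self):
        return dataset.make_pairs(self.images, self.annotations)

    def manifest(self) -> pd.DataFrame:
        rows = []
        for img_id, p in self.params.items():
            row = {"image_id": img_id, "roughness": p.roughness,
                   "glossiness": p.glossiness, "softness": p.softness,
                   "wetness": p.wetness, "granularity": p.granularity,
                   "seed": p.seed}
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        for img_id, img in self.images.items():
            Image.fromarray(img).save(out_dir / "images" / f"{img_id}.png")
        dataset.write_annotations_tsv(self.annotations, out_dir / "annotations.tsv")
        dataset.write_lexicon_tsv(self.lexicon(), out_dir / "lexicon.tsv")
        self.manifest().to_csv(out_dir / "manifest.tsv", sep="\t", index=False,
                               float_format="%.17g")

    @classmethod
    def read(cls, out_dir) -> "SyntheticCorpus":
        out_dir = Path(out_dir)
        manifest = pd.read_csv(out_dir / "manifest.tsv", sep="\t",
                               dtype={"image_id": str},
                               float_precision="round_trip")
        images, params = {}, {}
        for r in manifest.itertuples():
            images[r.image_id] = np.asarray(
                Image.open(out_dir / "images" / f"{r.image_id}.png"))
            params[r.image_id] = TextureParams(
                r.roughness, r.glossiness, r.softness, r.wetness,
                r.granularity, int(r.seed))
        annotations = dataset.read_annotations_tsv(out_dir / "annotations.tsv")
        return cls(images, annotations, params)


def gen_corpus(n_images: int, seed: int = 0, annotators: int = 10,
               size: int = 150, rules: AssociationRules = None) -> SyntheticCorpus:
    """Generate a corpus of ``n_images`` textures with simulated annotations.

    Perceptual parameters are drawn uniformly in [0, 1] per image; every
    image gets its own derived seed so the corpus is reproducible as a whole
    and per image.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    rules = rules or AssociationRules()
    master = np.random.default_rng(seed)
    images, annotations, params = {}, [], {}
    for i in range(n_images):
        img_id = f"img{i:04d}"
        p = TextureParams(*master.uniform(0, 1, 5),
                          seed=int(master.integers(0, 2 ** 31 - 1)))
        params[img_id] = p
        images[img_id] = gen_texture(p, size=size)
        annotations.extend(simulate_annotations(
            p, rules, annotators=annotators,
            seed=int(master.integers(0, 2 ** 31 - 1)), image_id=img_id))
    return SyntheticCorpus(images, annotations, params, rules)
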