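# Methods

## Phonological representation

A Japanese sound-symbolic word (SSW) is reduced to the first two morae of
its repetition unit.  Each mora is a consonant slot (possibly empty), a
vowel, and a set of trailing special phonemes (/N/ moraic nasal, /Q/
geminate, /R/ long vowel; slot 2 additionally /Li/, the word-final "-ri"
ending as in *shitto-ri*).  A single repetition bit distinguishes
reduplicated words (*gowa-gowa*) from simple ones (*puni*).  The canonical
inventory order is fixed — vowels /a i u e o/; consonants /k ky g gy s sy z
zy t ty d dy n ny h hy b by p py m my y r ry w/ plus explicit absence — and
every one-hot index derives from it.

Encoding lays the slots out as v1(5) c1(27) s1(3) v2(5) c2(27) s2(4) r(1),
72 bits, followed by a 16-bit block h: the 72 bits are rendered as a
'0'/'1' character string in layout order, hashed with MD5, and the first 16
digest bits are taken most-significant-bit first.  The digest serialization
(character string, MSB-first prefix) is our choice; any fixed deterministic
choice works, and the tests freeze independently computed digest values so
the convention cannot drift silently.  Since each output head of the
network is trained independently, h is the only place where cross-slot
correlations enter the code; two words with identical per-slot fit but
different hash bits are separated when candidates are ranked.

### Romanization

Input is Hepburn-style romaji.  *fu* maps to the /h/ row, *shi/sha/...* to
/sy/, *chi/cha/...* to /ty/, *tsu* to /t/+/u/, *ji/ja/...* to /zy/;
phonemic spellings (*sya*, *tya*, *hu*) are accepted too.  Repetition is
marked by a hyphen or by exact doubling (*gowagowa*).  Rendering emits a
canonical Hepburn form and is exactly inverted by parsing; three
disambiguation conventions keep the round trip lossless: an apostrophe
separates a moraic nasal from a following vowel or /y/ (*zan'ya*) and a
vowel-initial second mora from an identical preceding vowel (*sa'a*), and a
geminate with nothing safe to double (word-final, or before a vowel or
/n/-row onset) is written `q`.  Units of one mora are rejected — the code
has exactly two mora slots — and units longer than two morae are truncated
to the first two except for the /Li/ ending.  A 20,000-form randomized
round-trip check backs these rules.

## Scoring

For raw network output x and target bits t, the score is the sum of
softmax cross-entropies over v1, c1, v2, c2 and Bernoulli (sigmoid)
cross-entropies over every bit of s1, s2, r, h.  Both the training loss and
the candidate score use this same definition; they are implemented twice
independently (batched training path, scalar scoring path) and the suite
checks them against a brute-force elementwise oracle to 1e-9.  All
log-domain quantities use `logsumexp`/`log1p`-stable forms.  Lexicon
ranking sorts ascending by score with ties broken by corpus frequency, then
lexicographically.

Enumeration of candidate words directly from a probability table restricts
each softmax slot to its `depth` most probable elements (each binary slot
to both states when `depth` > 1) and lists all combinations in descending
product-of-probabilities order.  Treating `depth` as a per-slot rank bound
rather than a global candidate count is a deliberate design choice: it
makes `depth=1` coincide exactly with argmax decoding and yields the
expected near neighbours (e.g. *zara-zara* for the published example
table) without committing to a total order the underlying procedure does
not define.

## Network and training

Two backbones share one interface: a VGG16-style stack (13 conv layers, 3
FC layers, 224 px input) and a small test backbone (two 3×3 conv + pool
stages at 64 px, FC 256-128-88).  Dropout 0.5 is applied after the first
two FC layers only.  Defaults mirror the full-scale regime: SGD with batch
40, momentum 0.5, learning rate 2.5e-6, 100 epochs, conv layers frozen.
The layers (convolution via im2col, max pooling, dense, inverted dropout)
and the optimizer are implemented in NumPy inside the package; gradients
are verified against finite differences in the suite.  The small profile
uses learning rate 0.01 — appropriate for its randomly initialized
feature scale — and its 64 px input is deliberately not smaller: the
roughness signal lives in high spatial frequencies that stronger
downsampling would average away.

With frozen conv layers the stack is a fixed random feature extractor, so
features are computed once per unique image and standardized per dimension
with training-fold statistics (std floored at 1e-2 so near-constant ReLU
dimensions cannot explode off-fold).  The VGG16 profile is built with
random initialization; loading pretrained weights is a runtime option, and
no test depends on it.

Fold assignment shuffles image ids (seeded) and partitions them, so an
image never spans train and test; every annotated token is one training
pair, duplicates included.  Nominal k-fold bookkeeping puts round(n/k)
images in the held-out share — 1,751/195 for a 1,946-image corpus under
10-fold validation.  Two fits with the same seed produce bit-identical
curves.

## Synthetic corpus

The generator emulates the study design — 10 annotators per image, each
answering 1–6 SSWs — on procedural textures parameterized by roughness,
glossiness, softness, wetness and granularity, all in [0, 1] and drawn
uniformly per image.  Textures are spectrally synthesized noise: the power
spectrum follows 1/f^β with β = 2.6 − 2.0·roughness, relief amplitude grows
with roughness, granularity sets the feature scale, glossiness adds
specular-like highlights, softness blurs, wetness darkens.

Annotators sample each slot independently from softmax/sigmoid
distributions over rule-induced logits (association strength 6.0 by
default): voiced consonants rise with roughness and voiceless ones with
smoothness; /p/, /b/, /n/ with soft-and-wet; /k/ and the /t/-row with
hard-slippery-dry; /u/ with softness; /o/, /a/ with rough-hard-dry; /i/,
/e/ with negative (rough, matte) surfaces; long vowels lean soft and
geminates hard.  Resting preferences make palatalized rows and
vowel-initial morae rare and /e/ uncommon, as in real texture vocabulary.
Repetition is on with probability ≈ 0.92.

What the generator does *not* reproduce: a conventionalized shared
vocabulary.  Because slots are sampled independently, the type distribution
is far flatter than a human corpus (about 2 tokens per type at 200 images
versus ~16 in elicited data), there is no annotator idiosyncrasy, no
image-specific salience, and the textures are stationary noise rather than
photographs of materials.  Passing the recovery tests therefore shows the
pipeline can extract planted, learnable sound-symbolic structure — not
that it reaches human-corpus accuracy.  On this synthetic task the
information ceiling is itself modest: ranking with the *true* generative
logits reaches rank-1 accuracy ≈ 0.40 against a ≈ 0.10 permutation
baseline, so the trained small model's ≈ 0.15–0.22 against ≈ 0.06–0.10 is
meaningful signal, far from saturation.

## Evaluation

A ranked candidate is correct iff its canonical romanization is among the
words actually answered for that image (set membership, no phonological
distance).  Accuracy at rank k is the fraction of images whose k-th
candidate is correct; when several folds are evaluated, per-fold accuracies
are averaged rather than pooled.  The label-permutation baseline keeps the
ranked candidates and permutes the image → answered-set assignment (20
permutations, seeded), estimating the accuracy of an equally shaped but
uninformed predictor.  Per-epoch accuracy curves are produced by re-scoring
stored head checkpoints against the fixed lexicon.

## Problem sizes and determinism

The shipped experiments use a 200-image corpus (≈ 7,000 annotated tokens),
the small backbone, 10 epochs, and one of five folds (160 train / 40 test
images) — sizes chosen so the full loop, including the brute-force oracle
comparisons, runs in well under a minute on one CPU while leaving the
directional effects (loss decrease, accuracy over baseline,
voiced-consonant recovery) clearly resolved.  Every random draw — texture
fields, annotator choices, weight initialization, minibatch order, dropout
masks, permutation baselines — flows from explicit integer seeds, and the
acceptance script derives all of its seeds from a single `--seed`.

## Known limitations

- The hash head makes per-slot probabilities non-calibrated near decision
  boundaries: h is deterministic given the core bits, but the network
  predicts it independently, so argmax decoding ignores h entirely (it only
  informs ranking).
- Parsing targets two-mora SSW units; general Japanese vocabulary (single
  morae, 4-mora units without /Li/) is out of scope and rejected or
  truncated.
- The VGG16 profile is faithful in structure but starts from random
  weights; nothing here reproduces ImageNet-pretrained behaviour.
- Softness-blur and roughness-amplitude interact in the texture model, so
  extreme parameter combinations (very soft *and* very rough) are less
  visually distinct than their parameters suggest.
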