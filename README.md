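# sswvision

Express the texture of an image with Japanese sound-symbolic words.

Japanese sound-symbolic words (SSWs, onomatopoeia) describe texture at a
resolution adjectives cannot: *zara-zara* is dry, rough and unpleasant,
*sara-sara* dry but smooth and pleasant, *fuwa-fuwa* light and fluffy.
Their phonemes carry the meaning systematically — voiced obstruents (/g/,
/z/) evoke roughness, voiceless ones (/s/, /ts/) smoothness, the back vowel
/u/ soft pleasant feelings, bilabial plosives and /n/ soft, sticky and wet
ones.  `sswvision` is a computer-vision pipeline for researchers in texture
perception and computational psycholinguistics that exploits this: instead
of classifying a texture image into a fixed label set, a CNN predicts the
*probability distribution over phonemes* of the words people would use, and
SSWs are decoded or ranked from that distribution.

## The model

An SSW is represented by the first two morae of its repetition unit as an
88-dimensional binary vector

| block | dims | content |
|-------|------|---------|
| v1, v2 | 5 + 5 | one-hot vowels (/a/ /i/ /u/ /e/ /o/) of morae 1, 2 |
| c1, c2 | 27 + 27 | one-hot consonants (25 consonant rows, palatalized rows, or absence) |
| s1, s2 | 3 + 4 | multi-hot special phonemes /N/ /Q/ /R/ (+ /Li/ in slot 2) |
| r | 1 | repetition flag (*gowa-gowa* vs *puni*) |
| h | 16 | MD5 hash of the 72 bits above |

The network (a VGG16-style stack of 13 conv + 3 FC layers, or a small
two-conv test backbone; both implemented in NumPy) outputs one raw
88-vector.  Training minimizes the composite cross-entropy

L(x, t) = Σ_{G ∈ {v1,c1,v2,c2}} CE_softmax(x_G, t_G) + Σ_{G ∈ {s1,s2,r,h}} CE_sigmoid(x_G, t_G)

by minibatch SGD (batch 40, momentum 0.5, dropout 0.5 on the first two FC
layers, conv layers frozen), with one training pair per annotated SSW token.
The hash block h is the interesting part: the per-slot outputs are
independent, so *h* — a 16-bit MD5 digest of the rest of the code — is the
only head that can express correlations between slots, and it penalizes
phonotactically implausible phoneme combinations when candidates are ranked.

Given a trained model, the same cross-entropy scores any (image, word)
pair, so a lexicon of answered word types can be ranked per image; the
lowest-loss words are the system's first/second/third candidate SSWs, and a
candidate is *correct* when the annotators of that image actually answered
it.

Because the original human-annotated corpus (150×150 crops of material
photographs with ~29k answered SSW tokens) is not publicly deposited, the
package ships a first-class synthetic module: procedural textures with
controllable roughness / glossiness / softness / wetness / granularity, and
simulated annotators whose phoneme choices follow the documented
sound-symbolic associations.  The planted associations make the whole
train → predict → evaluate loop testable, including parameter recovery.

## Worked example

```python
import numpy as np
from sswvision import phonology, synthetic, model, dataset, evaluation

# 200 synthetic textures, 10 simulated annotators each
corpus = synthetic.gen_corpus(200, seed=0, annotators=10)
lex = corpus.lexicon()                      # answered types -> counts
forms = dataset.lexicon_forms(lex)

cfg = model.ModelConfig.small_test(epochs=10, seed=0)
tm = model.TexturePhonologyModel(corpus.pairs(), cfg)
res = tm.fit(folds=5, fit_folds=[0], lexicon=forms, counts=lex,
             answered=corpus.answered_sets())
print(res.summary())
```

```
Texture -> sound-symbolic word model
====================================================
backbone               small    frozen conv  True
epochs                    10    batch size   40
learning rate           0.01    momentum     0.5
dropout                  0.5    seed         0
folds                      1
----------------------------------------------------
fold  final train loss  final test loss   acc1   acc2
   0            18.7669          19.8188  0.150  0.150
```

Ranking the lexicon for held-out images shows the sound symbolism the model
picked up — voiced consonants for rough surfaces, voiceless /p/, /s/ for
smooth soft ones:

```python
fr = res.folds[0]
raw, _ = fr.model.predict([tm.images[i] for i in fr.test_ids])
ranked = evaluation.rank_images(raw, fr.test_ids, forms, k=3, counts=lex)
```

```
img0000  rough=0.64 soft=0.04  ->  zoga-zoga (18.12)  gozo-gozo (18.15)  gaza-gaza (18.20)
img0039  rough=0.09 soft=0.20  ->  pupu-pupu (14.70)  pusu-pusu (15.63)  supu-supu (15.75)
img0060  rough=0.82 soft=0.48  ->  gobu-gobu (18.00)  daga-daga (18.06)  baba-baba (18.08)
```

On this run the rank-1 candidate accuracy on the 40 held-out images is
0.150 against a label-permutation baseline of 0.059 — the numbers printed
by `evaluation.candidate_accuracy` and `evaluation.permutation_baseline`.
The losses next to each word are the composite cross-entropies used for
ranking (lower = better fit to the predicted phoneme distribution).

A command-line interface wraps the same pipeline:

```
ssw-texture encode gowa-gowa          # 88-bit vector
ssw-texture decode --probs out.csv    # argmax word of a probability vector
ssw-texture synth --n-images 40 --seed 1 --out corpus/
ssw-texture train --corpus corpus/ --epochs 10 --out model.npz
ssw-texture predict --model model.npz --image corpus/images/img0000.png
ssw-texture evaluate --model model.npz --corpus corpus/ --out results.csv
```

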