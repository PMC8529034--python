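"""Accuracy evaluation: lexicon-restricted candidate ranking and curves.

A candidate word produced for an image counts as correct when it belongs to
the set of words human (or simulated) annotators actually answered for that
image — membership after canonical romanization, not phonological distance.
Rank-k accuracy is the fraction of images whose k-th ranked candidate (by
ascending cross-entropy over a fixed lexicon) is correct.  The
label-permutation baseline reruns the same scoring with answer sets randomly
reassigned across images and serves as the no-signal reference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import phonology
from .phonology import EmptyLexicon, render_ssw

__all__ = [
    "MissingAnswers", "rank_images", "candidate_accuracy", "results_table",
    "accuracy_curves", "permutation_baseline",
]


class MissingAnswers(ValueError):
    pass


def rank_images(raw_outputs, image_ids, lexicon, k: int = 3, counts=None,
                targets=None):
    """Rank lexicon candidates for each image's raw output.

    Returns ``{image_id: [(word, loss), ...]}`` with ``k`` entries per image,
    ascending in loss; ties break toward higher lexicon frequency
    (``counts``), then lexicographically.  ``targets`` may carry the
    pre-encoded (L, 88) lexicon matrix to avoid re-encoding.
    """
    lexicon = list(lexicon)
    if not lexicon:
        raise EmptyLexicon("ranking requires a non-empty lexicon")
    words = [render_ssw(f) for f in lexicon]
    if targets is None:
        targets = np.stack([phonology.encode_ssw(f) for f in lexicon]).astype(float)
    losses = phonology.score_matrix(np.atleast_2d(raw_outputs), targets)
    counts = counts or {}
    freq = np.array([counts.get(w, 0) for w in words])
    word_rank = np.argsort(np.argsort(words))  # lexicographic tie-break key
    ranked = {}
    for row, img_id in zip(losses, image_ids):
        order = np.lexsort((word_rank, -freq, row))[:k]
        ranked[img_id] = [(words[j], float(row[j])) for j in order]
    return ranked


def candidate_accuracy(ranked, answered, rank: int = 1) -> float:
    """Fraction of images whose rank-th (1-based) candidate was answered."""
    if not ranked:
        raise MissingAnswers("no ranked images to evaluate")
    hits, n = 0, 0
    for img_id, cands in ranked.items():
        if img_id not in answered or not answered[img_id]:
            raise MissingAnswers(f"no answered SSWs for image {img_id}")
        ans = {phonology.canonicalize(w) for w in answered[img_id]}
        if len(cands) >= rank and cands[rank - 1][0] in ans:
            hits += 1
        n += 1
    return hits / n


def results_table(ranked, answered) -> pd.DataFrame:
    """Long-format results: image_id, rank, candidate, loss, correct."""
    rows = []
    for img_id, cands in sorted(ranked.items(), key=lambda kv: str(kv[0])):
        ans = {phonology.canonicalize(w) for w in answered.get(img_id, ())}
        for r, (word, loss) in enumerate(cands, start=1):
            rows.append({"image_id": img_id, "rank": r, "candidate": word,
                         "loss": loss, "correct": word in ans})
    return pd.DataFrame(rows)


def accuracy_curves(fold_result, texmodel, lexicon, answered,
                    counts=None) -> pd.DataFrame:
    """Per-epoch rank-1/rank-2 accuracy on a fold's held-out images.

    ``fold_result`` must have been fitted with ``keep_checkpoints=True``;
    each stored head checkpoint is evaluated against the fixed lexicon.
    Returns a frame with one row per checkpoint: epoch, acc1, acc2.
    """
    if not fold_result.checkpoints:
        raise ValueError("fold was fitted without keep_checkpoints=True")
    model = fold_result.model
    eval_ids = fold_result.test_ids
    if not eval_ids:
        raise MissingAnswers("fold has no held-out images")
    lexicon = list(lexicon)
    targets = np.stack([phonology.encode_ssw(f) for f in lexicon]).astype(float)
    feats = model.features([texmodel.images[i] for i in eval_ids])
    current = model.head_snapshot()
    records = []
    try:
        for epoch, snap in enumerate(fold_result.checkpoints, start=1):
            model.load_head_snapshot(snap)
            raw = model.head_forward(feats, train=False)
            ranked = rank_images(raw, eval_ids, lexicon, k=2, counts=counts,
                                 targets=targets)
            records.append({"epoch": epoch,
                            "acc1": candidate_accuracy(ranked, answered, 1),
                            "acc2": candidate_accuracy(ranked, answered, 2)})
    finally:
        model.load_head_snapshot(current)
    return pd.DataFrame.from_records(records)


def permutation_baseline(ranked, answered, rank: int = 1, seed: int = 0,
                         n_permutations: int = 20) -> float:
    """Mean accuracy after shuffling answer sets across images.

    The same ranked candidates are kept; only the image -> answered-set
    assignment is permuted, so the value estimates the accuracy a no-signal
    model of identical output statistics would reach.
    """
    rng = np.random.default_rng(seed)
    ids = sorted(ranked, key=str)
    accs = []
    for _ in range(n_permutations):
        perm = rng.permutation(len(ids))
        shuffled = {ids[i]: answered[ids[j]] for i, j in enumerate(perm)}
        accs.append(candidate_accuracy(ranked, shuffled, rank))
    return float(np.mean(accs))
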