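"""Corpus building: mark-based crops, annotation I/O, lexicon, train/test folds.

The source corpus pipeline: participants mark the image region they focused
on while describing its texture with sound-symbolic words; regions marked by
at least three distinct participants are cropped to fixed 150x150 squares,
and every annotated SSW token becomes one (image, phonological-vector)
training pair.  File formats are plain TSV throughout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from . import phonology
from .phonology import UnparseableSSW

__all__ = [
    "MarkRecord", "AnnotationRecord", "ImageTooSmall", "MissingImage",
    "crop_marked_regions", "build_lexicon", "lexicon_forms", "make_pairs",
    "nominal_fold_sizes",
    "read_marks_tsv", "write_marks_tsv", "read_annotations_tsv",
    "write_annotations_tsv", "read_lexicon_tsv", "write_lexicon_tsv",
]


class ImageTooSmall(ValueError):
    pass


class MissingImage(KeyError):
    pass


@dataclass(frozen=True)
class MarkRecord:
    """A point a participant marked on an image (0-based, origin top-left)."""

    image_id: str
    participant_id: str
    x: int
    y: int


@dataclass(frozen=True)
class AnnotationRecord:
    """The 1-6 SSW tokens one participant answered for one image."""

    image_id: str
    participant_id: str
    tokens: tuple

    def __post_init__(self):
        object.__setattr__(self, "tokens", tuple(self.tokens))
        if not 1 <= len(self.tokens) <= 6:
            raise ValueError(
                f"a participant answers 1-6 SSWs per image, got {len(self.tokens)}")


# ---------------------------------------------------------------------------
# Cropping


def crop_marked_regions(image, marks, min_marks: int = 3, crop_size: int = 150):
    """Crop fixed-size squares around clusters of participant marks.

    Marks are clustered by single linkage with a link distance of
    ``crop_size / 2``; each cluster marked by at least ``min_marks`` distinct
    participants yields one ``crop_size`` square centered on the cluster
    centroid and clamped to the image bounds.  Returns the crops ordered by
    cluster centroid (top-left first).
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h < crop_size or w < crop_size:
        raise ImageTooSmall(f"image {w}x{h} is smaller than the {crop_size} crop")
    marks = list(marks)
    if not marks:
        return []
    pts = np.array([(m.x, m.y) for m in marks], dtype=float)
    for m in marks:
        if not (0 <= m.x < w and 0 <= m.y < h):
            raise ValueError(f"mark ({m.x}, {m.y}) outside image bounds {w}x{h}")
    if len(marks) == 1:
        labels = np.array([1])
    else:
        labels = fcluster(linkage(pts, method="single"),
                          t=crop_size / 2.0, criterion="distance")
    crops = []
    for lab in np.unique(labels):
        sel = labels == lab
        participants = {marks[i].participant_id for i in np.flatnonzero(sel)}
        if len(participants) < min_marks:
            continue
        cx, cy = pts[sel].mean(axis=0)
        x0 = int(round(cx - crop_size / 2.0))
        y0 = int(round(cy - crop_size / 2.0))
        x0 = min(max(x0, 0), w - crop_size)
        y0 = min(max(y0, 0), h - crop_size)
        crops.append(((y0, x0), image[y0:y0 + crop_size, x0:x0 + crop_size]))
    crops.sort(key=lambda c: c[0])
    return [c[1] for c in crops]


# ---------------------------------------------------------------------------
# Lexicon and pairs


def build_lexicon(annotations, skip_unparseable: bool = False) -> Counter:
    """Count SSW types over all annotation tokens after canonicalization.

    Tokens that differ only in spelling ("gowagowa" vs "gowa-gowa") collapse
    to one type.  Unparseable tokens raise with row context unless
    ``skip_unparseable``.
    """
    counts = Counter()
    for rec in annotations:
        for tok in rec.tokens:
            try:
                counts[phonology.canonicalize(tok)] += 1
            except UnparseableSSW as exc:
                if skip_unparseable:
                    continue
                raise UnparseableSSW(
                    f"image {rec.image_id}, participant {rec.participant_id}: "
                    f"{exc}") from exc
    return counts


def lexicon_forms(lexicon) -> list:
    """Parsed forms for a lexicon mapping/iterable of word strings."""
    return [phonology.parse_ssw(w) for w in lexicon]


def make_pairs(images: dict, annotations, skip_unparseable: bool = False):
    """One (image_id, image, 88-bit target) triple per annotated token."""
    pairs = []
    for rec in annotations:
        if rec.image_id not in images:
            raise MissingImage(rec.image_id)
        img = images[rec.image_id]
        for tok in rec.tokens:
            try:
                form = phonology.parse_ssw(tok)
            except UnparseableSSW:
                if skip_unparseable:
                    continue
                raise
            pairs.append((rec.image_id, img, phonology.encode_ssw(form)))
    return pairs


def nominal_fold_sizes(n_images: int, folds: int = 10):
    """Nominal (train, test) image counts for k-fold cross-validation.

    The held-out share is ``round(n / folds)``; e.g. 1,946 images under
    10-fold validation give a 1,751 / 195 split.
    """
    test = int(round(n_images / folds))
    return n_images - test, test


# ---------------------------------------------------------------------------
# TSV I/O


def write_marks_tsv(marks, path) -> None:
    pd.DataFrame([{"image_id": m.image_id, "participant_id": m.participant_id,
                   "x": m.x, "y": m.y} for m in marks]).to_csv(
        path, sep="\t", index=False)


def read_marks_tsv(path):
    df = pd.read_csv(path, sep="\t", dtype={"image_id": str, "participant_id": str})
    return [MarkRecord(r.image_id, r.participant_id, int(r.x), int(r.y))
            for r in df.itertuples()]


def write_annotations_tsv(annotations, path) -> None:
    pd.DataFrame([{"image_id": a.image_id, "participant_id": a.participant_id,
                   "ssws": ";".join(a.tokens)} for a in annotations]).to_csv(
        path, sep="\t", index=False)


def read_annotations_tsv(path):
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [AnnotationRecord(r.image_id, r.participant_id,
                             tuple(r.ssws.split(";")))
            for r in df.itertuples()]


def write_lexicon_tsv(lexicon, path) -> None:
    """Write ``ssw<TAB>count`` rows, most frequent first."""
    items = sorted(lexicon.items(), key=lambda kv: (-kv[1], kv[0]))
    pd.DataFrame(items, columns=["ssw", "count"]).to_csv(path, sep="\t", index=False)


def read_lexicon_tsv(path) -> Counter:
    df = pd.read_csv(path, sep="\t", dtype={"ssw": str, "count": int})
    return Counter(dict(zip(df["ssw"], df["count"])))
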