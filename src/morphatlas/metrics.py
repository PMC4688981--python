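"""Overlap similarity indices between an automatic segmentation and gold standard.

Three voxel-count overlap ratios are used:

* Dice similarity coefficient  DSC(A, B) = 2|A∩B| / (|A| + |B|)
* Jaccard index                JI(A, B)  = |A∩B| / |A∪B|
* Inclusion index              INI(A, B) = |A∩B| / |A|

DSC and JI are symmetric and penalise false positives; INI is asymmetric —
its first argument is the gold standard — and gives no penalty for a false
positive delineation (any automatic mask covering the gold standard scores 1).
Counts are taken on the shared grid; because both masks live on the same
grid the physical voxel volume cancels in every ratio.

Empty-mask degeneracies raise :class:`~morphatlas.volume.UndefinedMetricError`
rather than silently returning 0, since silent zeros would corrupt group means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import LabelVolume, UndefinedMetricError


@dataclass(frozen=True)
class SimilarityScores:
    """The (DSC, JI, INI) triple for one (gold, automatic) mask pair."""

    dsc: float
    ji: float
    ini: float


def _counts(gold: LabelVolume, auto: LabelVolume) -> tuple[int, int, int]:
    gold.require_same_grid(auto)
    a = gold.voxels.astype(bool)
    b = auto.voxels.astype(bool)
    return int(a.sum()), int(b.sum()), int((a & b).sum())


def dice(gold: LabelVolume, auto: LabelVolume) -> float:
    """Dice similarity coefficient, 2|A∩B| / (|A|+|B|)."""
    na, nb, ni = _counts(gold, auto)
    if na + nb == 0:
        raise UndefinedMetricError("Dice undefined: both masks are empty")
    return 2.0 * ni / (na + nb)


def jaccard(gold: LabelVolume, auto: LabelVolume) -> float:
    """Jaccard index, |A∩B| / |A∪B|."""
    na, nb, ni = _counts(gold, auto)
    union = na + nb - ni
    if union == 0:
        raise UndefinedMetricError("Jaccard undefined: both masks are empty")
    return ni / union


def inclusion(gold: LabelVolume, auto: LabelVolume) -> float:
    """Inclusion index, |A∩B| / |A|; the first argument is the gold standard."""
    na, _, ni = _counts(gold, auto)
    if na == 0:
        raise UndefinedMetricError("Inclusion undefined: empty gold standard")
    return ni / na


def score_pair(gold: LabelVolume, auto: LabelVolume) -> SimilarityScores:
    """All three indices for one (gold, automatic) pair."""
    na, nb, ni = _counts(gold, auto)
    if na == 0:
        raise UndefinedMetricError("scores undefined: empty gold standard")
    if na + nb == 0:  # pragma: no cover - subsumed by the gold check
        raise UndefinedMetricError("scores undefined: both masks empty")
    union = na + nb - ni
    return SimilarityScores(
        dsc=2.0 * ni / (na + nb),
        ji=ni / union,
        ini=ni / na,
    )
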