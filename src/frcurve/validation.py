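"""Position-level sensitivity/specificity of features against known
mis-assembled intervals.

The confusion matrix is per assembled position: a position is a true
positive when it lies inside a ground-truth mis-assembly interval and is
covered by at least one feature.  Sensitivity = TP/(TP+FN) measures how much
of the truly mis-assembled sequence the features recover; specificity =
TN/(TN+FP) how much correct sequence stays unflagged.  TP+FP+TN+FN always
equals the total assembled length.

``slack`` dilates truth intervals before scoring: breakpoint-type features
(e.g. mis-oriented pairs at an inversion edge) flank the event within about
one library insert length rather than covering its body, and slack credits
those calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .feature_detection import FeatureRegion

__all__ = ["TruthSet", "sensitivity_specificity"]


@dataclass
class TruthSet:
    """Ground-truth mis-assembly intervals in assembly coordinates.

    ``intervals``: (contig_id, start, end, event_type) with 0-based half-open
    coordinates; ``assembly_lengths`` maps every contig to its length.
    """

    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)
    assembly_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, start, end, _ in self.intervals:
            if cid not in self.assembly_lengths:
                raise ValueError(f"truth interval on unknown contig {cid!r}")
            if not (0 <= start < end <= self.assembly_lengths[cid]):
                raise ValueError(
                    f"truth interval [{start},{end}) outside contig {cid!r}")


def sensitivity_specificity(
    features: Sequence[FeatureRegion],
    truth: TruthSet,
    slack: int = 0,
) -> dict:
    """Per-position confusion matrix over all assembled positions.

    Returns sens, spec (None when the ratio is undefined, e.g. empty truth
    or everything flagged) and the TP/FP/TN/FN counts.
    """
    if slack < 0:
        raise ValueError("slack must be >= 0")
    flagged = {cid: np.zeros(n, dtype=bool)
               for cid, n in truth.assembly_lengths.items()}
    for r in features:
        if r.contig_id not in flagged:
            raise ValueError(f"feature on unknown contig {r.contig_id!r}")
        n = truth.assembly_lengths[r.contig_id]
        if r.end > n:
            raise ValueError(
                f"feature [{r.start},{r.end}) outside contig {r.contig_id!r}")
        flagged[r.contig_id][r.start:r.end] = True
    truthy = {cid: np.zeros(n, dtype=bool)
              for cid, n in truth.assembly_lengths.items()}
    for cid, start, end, _ in truth.intervals:
        n = truth.assembly_lengths[cid]
        truthy[cid][max(0, start - slack):min(n, end + slack)] = True
    tp = fp = tn = fn = 0
    for cid in truth.assembly_lengths:
        t, f = truthy[cid], flagged[cid]
        tp += int(np.sum(t & f))
        fn += int(np.sum(t & ~f))
        fp += int(np.sum(~t & f))
        tn += int(np.sum(~t & ~f))
    sens: Optional[float] = tp / (tp + fn) if (tp + fn) else None
    spec: Optional[float] = tn / (tn + fp) if (tn + fp) else None
    return {"sens": sens, "spec": spec, "tp": tp, "fp": fp, "tn": tn, "fn": fn}
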