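"""Feature Response Curves and assembly summary statistics.

The Feature Response Curve (FRCurve) captures the trade-off between
contiguity and correctness: contigs are sorted from longest to shortest and,
for each feature threshold tau, the longest prefix whose cumulative feature
count stays within tau is tallied; its total length over the estimated
genome size is the approximate genome coverage — one curve point.  A steeper
curve means more of the genome is recovered at a low feature budget.

The cumulative-count comparison is inclusive (``<= tau``) so that tau=0
means "contigs carrying no features"; swept over integer tau this yields the
same point set as a strict sweep shifted by one.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .feature_detection import FeatureRegion, FeatureType

__all__ = [
    "ContigSummary",
    "FRCurvePoint",
    "compute_frcurve",
    "summaries_from_regions",
    "per_feature_curves",
    "assembly_summary",
]

CHAFF_CUTOFF = 200  # bp; contigs shorter than this are "chaff"


@dataclass(frozen=True)
class ContigSummary:
    contig_id: str
    length: int
    feature_count: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("contig length must be > 0")
        if self.feature_count < 0:
            raise ValueError("feature_count must be >= 0")


@dataclass(frozen=True)
class FRCurvePoint:
    tau: int
    coverage: float  # approximate genome coverage in [0, 1]


def compute_frcurve(
    summaries: Sequence[ContigSummary],
    genome_size: int,
    tau_values: Optional[Sequence[int]] = None,
) -> list[FRCurvePoint]:
    """One curve point per tau: coverage of the longest contigs whose
    cumulative feature count is <= tau.

    Contigs are sorted by length descending (ties broken by id for
    determinism).  ``tau_values`` defaults to every integer from 0 to the
    total feature count, so the curve reaches its plateau
    ``min(1, sum(lengths)/genome_size)``.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    if not summaries:
        raise ValueError("summaries must be non-empty")
    ordered = sorted(summaries, key=lambda s: (-s.length, s.contig_id))
    cum_feat: list[int] = []
    cum_len: list[int] = []
    f = l = 0
    for s in ordered:
        f += s.feature_count
        l += s.length
        cum_feat.append(f)
        cum_len.append(l)
    total = cum_feat[-1]
    if tau_values is None:
        tau_values = range(0, total + 1)
    points = []
    for tau in tau_values:
        # longest prefix with cum_feat <= tau (cum_feat is non-decreasing)
        import bisect
        k = bisect.bisect_right(cum_feat, tau)
        length = cum_len[k - 1] if k else 0
        points.append(FRCurvePoint(int(tau), min(1.0, length / genome_size)))
    return points


def summaries_from_regions(
    regions: Iterable[FeatureRegion],
    contig_lengths: Mapping[str, int],
    feature_type: Optional[FeatureType] = None,
) -> list[ContigSummary]:
    """Per-contig merged-region counts, optionally restricted to one type."""
    counts: Counter[str] = Counter()
    for r in regions:
        if feature_type is None or r.type is feature_type:
            counts[r.contig_id] += 1
    return [
        ContigSummary(cid, length, counts.get(cid, 0))
        for cid, length in contig_lengths.items()
    ]


def per_feature_curves(
    regions: Iterable[FeatureRegion],
    contig_lengths: Mapping[str, int],
    genome_size: int,
    tau_values: Optional[Sequence[int]] = None,
) -> dict[FeatureType, list[FRCurvePoint]]:
    """One FRCurve per feature type, counting only that type's regions."""
    regions = list(regions)
    return {
        ftype: compute_frcurve(
            summaries_from_regions(regions, contig_lengths, ftype),
            genome_size,
            tau_values,
        )
        for ftype in FeatureType
    }


def assembly_summary(
    contig_lengths: Sequence[int],
    genome_size: int,
    chaff_cutoff: int = CHAFF_CUTOFF,
) -> dict:
    """Contig count, NG50 and chaff percentage.

    NG50 is the length of the contig at which the cumulative sum of
    descending-sorted lengths first reaches half the genome size (0 when it
    never does).  Chaff is the summed length of contigs shorter than
    ``chaff_cutoff``, as a percentage of the genome size.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    lengths = sorted(contig_lengths, reverse=True)
    if not lengths:
        return {"n_contigs": 0, "NG50": 0, "chaff_pct": 0.0}
    ng50 = 0
    acc = 0
    half = genome_size / 2
    for l in lengths:
        acc += l
        if acc >= half:
            ng50 = l
            break
    chaff = sum(l for l in lengths if l < chaff_cutoff)
    return {
        "n_contigs": len(lengths),
        "NG50": ng50,
        "chaff_pct": 100.0 * chaff / genome_size,
    }
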