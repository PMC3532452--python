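"""Turn per-contig tracks into the 14 typed suspicious-region features.

Three detector families:

- coverage features (PE library only): per-position read / proper-pair
  coverage compared against a multiple of the library's own mean;
- compression/expansion (CE) features: a z-like statistic comparing the
  local mean of spanning fragment lengths to the library mean;
- pair-anomaly features: windowed excess of singleton, other-contig, or
  mis-oriented/too-distant reads.

Flagged evidence is merged into maximal regions per type; regions shorter
than ``min_region`` are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .core_model import ContigTracks, GlobalStats, LibraryProfile, LibraryRole

__all__ = [
    "FeatureType",
    "FeatureRegion",
    "Thresholds",
    "ce_statistic",
    "detect_coverage_features",
    "detect_ce_features",
    "detect_pair_anomaly_features",
    "merge_regions",
    "annotate_contig",
]


class FeatureType(str, Enum):
    LOW_COV_PE = "LOW_COV_PE"            # low read coverage (all aligned reads)
    HIGH_COV_PE = "HIGH_COV_PE"          # high read coverage (all aligned reads)
    LOW_NORM_COV_PE = "LOW_NORM_COV_PE"  # low coverage by properly paired reads
    HIGH_NORM_COV_PE = "HIGH_NORM_COV_PE"
    COMPR_PE = "COMPR_PE"                # low CE statistic on PE fragments
    STRECH_PE = "STRECH_PE"              # high CE statistic on PE fragments
    HIGH_SINGLE_PE = "HIGH_SINGLE_PE"    # excess reads with unmapped mate
    HIGH_SPAN_PE = "HIGH_SPAN_PE"        # excess reads with mate on another contig
    HIGH_OUTIE_PE = "HIGH_OUTIE_PE"      # excess mis-oriented / too-distant reads
    COMPR_MP = "COMPR_MP"
    STRECH_MP = "STRECH_MP"
    HIGH_SINGLE_MP = "HIGH_SINGLE_MP"
    HIGH_SPAN_MP = "HIGH_SPAN_MP"
    HIGH_OUTIE_MP = "HIGH_OUTIE_MP"

    @property
    def library_role(self) -> LibraryRole:
        return LibraryRole.MP if self.value.endswith("_MP") else LibraryRole.PE


PE_ONLY_TYPES = frozenset(
    t for t in FeatureType if t.library_role is LibraryRole.PE
)


@dataclass(frozen=True)
class FeatureRegion:
    """A typed, contiguous suspicious interval on a contig (0-based half-open).

    ``score`` is the mean offending statistic over the region (coverage for
    coverage features, Z for CE features, anomalous-read fraction otherwise).
    """

    contig_id: str
    start: int
    end: int
    type: FeatureType
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region [{self.start},{self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Thresholds:
    """Detector thresholds.  All values are package defaults and adjustable.

    ``cov_low_frac``/``cov_high_frac`` multiply the library's mean coverage;
    ``ce_low``/``ce_high`` bound the CE z-statistic; ``anomaly_frac`` is the
    minimum fraction of window reads in the offending class; regions closer
    than ``merge_gap`` are merged and merged regions shorter than
    ``min_region`` are dropped.
    """

    cov_low_frac: float = 1.0 / 3.0
    cov_high_frac: float = 3.0
    ce_low: float = -3.0
    ce_high: float = 3.0
    anomaly_frac: float = 0.4
    min_region: int = 200
    merge_gap: int = 200

    def __post_init__(self) -> None:
        if not (self.cov_low_frac < 1.0 < self.cov_high_frac):
            raise ValueError("need cov_low_frac < 1 < cov_high_frac")
        if not (self.ce_low < 0.0 < self.ce_high):
            raise ValueError("need ce_low < 0 < ce_high")
        if not (0.0 < self.anomaly_frac <= 1.0):
            raise ValueError("need 0 < anomaly_frac <= 1")


def ce_statistic(
    window_fragments: Sequence[float],
    lib: LibraryProfile,
    length_bias_correction: bool = False,
) -> Optional[float]:
    """Compression/expansion z-statistic for one window.

    ``Z = (m - mu) / (sigma / sqrt(n))`` where ``m`` is the local mean of the
    ``n`` fragment lengths spanning the window.  Negative Z signals local
    compression (assembly shorter than the sequenced template), positive Z a
    stretch/expansion.  Returns None for an empty window ("no data" is never
    conflated with "perfect", i.e. Z=0).

    When the fragments were sampled *because they span a locus*, the sample
    is length-biased and its null mean is ``mu + sigma^2/mu``, not ``mu``;
    ``length_bias_correction=True`` subtracts that offset so the null is
    centred.  Leave it off for plain i.i.d. samples.
    """
    n = len(window_fragments)
    if n == 0:
        return None
    if lib.insert_sd <= 0:
        raise ValueError("library insert_sd must be > 0")
    mu = lib.insert_mean
    if length_bias_correction:
        mu = mu + lib.insert_sd ** 2 / lib.insert_mean
    m = float(np.mean(window_fragments))
    return (m - mu) / (lib.insert_sd / math.sqrt(n))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean array, as half-open intervals."""
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def merge_regions(
    regions: Sequence[FeatureRegion],
    merge_gap: int,
    min_region: int,
) -> list[FeatureRegion]:
    """Merge same-type regions on one contig and drop short ones.

    Regions separated by a gap strictly smaller than ``merge_gap`` are
    merged (scores combine length-weighted); merged regions shorter than
    ``min_region`` are dropped.  Output is sorted and non-overlapping.
    """
    if not regions:
        return []
    types = {r.type for r in regions}
    contigs = {r.contig_id for r in regions}
    if len(types) > 1 or len(contigs) > 1:
        raise ValueError("merge_regions expects one contig and one feature type")
    ordered = sorted(regions, key=lambda r: (r.start, r.end))
    merged: list[FeatureRegion] = []
    cur_start, cur_end = ordered[0].start, ordered[0].end
    cur_score = ordered[0].score * len(ordered[0])
    cur_len = len(ordered[0])
    for r in ordered[1:]:
        if r.start - cur_end < merge_gap:
            cur_end = max(cur_end, r.end)
            cur_score += r.score * len(r)
            cur_len += len(r)
        else:
            merged.append(FeatureRegion(
                r.contig_id, cur_start, cur_end, r.type, cur_score / cur_len))
            cur_start, cur_end = r.start, r.end
            cur_score, cur_len = r.score * len(r), len(r)
    proto = ordered[0]
    merged.append(FeatureRegion(
        proto.contig_id, cur_start, cur_end, proto.type, cur_score / cur_len))
    return [r for r in merged if len(r) >= min_region]


def detect_coverage_features(
    tracks: ContigTracks,
    stats: GlobalStats,
    th: Thresholds = Thresholds(),
) -> list[FeatureRegion]:
    """Low/high (proper-pair) coverage regions.  PE tracks only.

    A position enters LOW_COV_PE iff its read coverage is below
    ``cov_low_frac * mean_read_cov`` and HIGH_COV_PE iff above
    ``cov_high_frac * mean_read_cov``; the *_NORM_* pair applies the same
    rule to proper-pair coverage and its mean.
    """
    if stats.mean_read_cov <= 0:
        raise ValueError("empty alignment")
    out: list[FeatureRegion] = []
    plans = [
        (tracks.read_cov, stats.mean_read_cov, FeatureType.LOW_COV_PE,
         FeatureType.HIGH_COV_PE),
        (tracks.proper_cov, stats.mean_proper_cov, FeatureType.LOW_NORM_COV_PE,
         FeatureType.HIGH_NORM_COV_PE),
    ]
    for cov, mean, low_t, high_t in plans:
        if mean <= 0:
            continue
        for ftype, mask in (
            (low_t, cov < th.cov_low_frac * mean),
            (high_t, cov > th.cov_high_frac * mean),
        ):
            raw = [
                FeatureRegion(tracks.contig_id, a, b, ftype,
                              float(cov[a:b].mean()))
                for a, b in _runs(mask)
            ]
            out.extend(merge_regions(raw, th.merge_gap, th.min_region))
    return out


def _window_stripe(tracks: ContigTracks, i: int) -> tuple[int, int]:
    """The step-resolution stripe a window's midpoint sample localises.

    Windows on the default grid overlap (step < window); flagging the whole
    window would mark each anomalous locus up to window/step times over.  The
    stripe of width ``step`` centred on the midpoint tiles the contig, so
    contiguous flagged windows still merge into full-extent regions.  With a
    non-overlapping grid (step >= window) the stripe is the window itself.
    """
    a, b = tracks.windows[i]
    if tracks.step >= tracks.window:
        return a, b
    mid = int(tracks.window_midpoints[i])
    lo = max(a, mid - tracks.step // 2)
    hi = min(b, lo + tracks.step)
    return lo, hi


def detect_ce_features(
    tracks: ContigTracks,
    lib: LibraryProfile,
    th: Thresholds = Thresholds(),
    length_bias_correction: bool = True,
) -> list[FeatureRegion]:
    """Compression (Z < ce_low) and stretch (Z > ce_high) regions.

    Windows without spanning fragments yield no CE evidence (absence of
    evidence is not compression).  The feature-type suffix follows the
    library role.
    """
    compr = FeatureType.COMPR_MP if lib.role is LibraryRole.MP else FeatureType.COMPR_PE
    strech = FeatureType.STRECH_MP if lib.role is LibraryRole.MP else FeatureType.STRECH_PE
    raw: dict[FeatureType, list[FeatureRegion]] = {compr: [], strech: []}
    for i, frs in enumerate(tracks.window_inserts):
        z = ce_statistic(frs, lib, length_bias_correction=length_bias_correction)
        if z is None:
            continue
        ftype = compr if z < th.ce_low else strech if z > th.ce_high else None
        if ftype is None:
            continue
        a, b = _window_stripe(tracks, i)
        raw[ftype].append(FeatureRegion(tracks.contig_id, a, b, ftype, z))
    out: list[FeatureRegion] = []
    for ftype, regions in raw.items():
        out.extend(merge_regions(regions, max(th.merge_gap, 1), th.min_region))
    return out


_ANOMALY_TRACKS = {
    "singleton_cnt": (FeatureType.HIGH_SINGLE_PE, FeatureType.HIGH_SINGLE_MP),
    "spanning_cnt": (FeatureType.HIGH_SPAN_PE, FeatureType.HIGH_SPAN_MP),
    "outie_cnt": (FeatureType.HIGH_OUTIE_PE, FeatureType.HIGH_OUTIE_MP),
}


def detect_pair_anomaly_features(
    tracks: ContigTracks,
    lib: LibraryProfile,
    th: Thresholds = Thresholds(),
) -> list[FeatureRegion]:
    """Windows where the offending-class read fraction exceeds ``anomaly_frac``.

    The fraction is (class base-count)/(read base-count) summed over the
    window; windows with zero read coverage are skipped.
    """
    is_mp = lib.role is LibraryRole.MP
    # windowed sums via cumulative arrays
    ccov = np.concatenate([[0], np.cumsum(tracks.read_cov)])
    out: list[FeatureRegion] = []
    for attr, (pe_t, mp_t) in _ANOMALY_TRACKS.items():
        ftype = mp_t if is_mp else pe_t
        cnt = getattr(tracks, attr)
        ccnt = np.concatenate([[0], np.cumsum(cnt)])
        raw: list[FeatureRegion] = []
        for i, (a, b) in enumerate(tracks.windows):
            denom = ccov[b] - ccov[a]
            if denom == 0:
                continue
            frac = (ccnt[b] - ccnt[a]) / denom
            if frac > th.anomaly_frac:
                lo, hi = _window_stripe(tracks, i)
                raw.append(FeatureRegion(tracks.contig_id, lo, hi, ftype, frac))
        out.extend(merge_regions(raw, max(th.merge_gap, 1), th.min_region))
    return out


def annotate_contig(
    tracks_pe: ContigTracks,
    stats_pe: GlobalStats,
    lib_pe: LibraryProfile,
    tracks_mp: Optional[ContigTracks] = None,
    stats_mp: Optional[GlobalStats] = None,
    lib_mp: Optional[LibraryProfile] = None,
    th: Thresholds = Thresholds(),
) -> list[FeatureRegion]:
    """All features for one contig: the three detectors, PE and (if given) MP.

    Coverage features come from the PE library only; CE and pair-anomaly
    features are computed per library with the matching type suffix.  CE uses
    the refined insert statistics when available.
    """
    def refined(lib: LibraryProfile, stats: Optional[GlobalStats]) -> LibraryProfile:
        if stats is None or stats.n_fragments < 2:
            return lib
        return lib.with_insert(stats.insert_mean, stats.insert_sd)

    out = list(detect_coverage_features(tracks_pe, stats_pe, th))
    out += detect_ce_features(tracks_pe, refined(lib_pe, stats_pe), th)
    out += detect_pair_anomaly_features(tracks_pe, lib_pe, th)
    if tracks_mp is not None:
        if lib_mp is None:
            raise ValueError("MP tracks supplied without an MP library profile")
        out += detect_ce_features(tracks_mp, refined(lib_mp, stats_mp), th)
        out += detect_pair_anomaly_features(tracks_mp, lib_mp, th)
    return sorted(out, key=lambda r: (r.start, r.end, r.type.value))
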