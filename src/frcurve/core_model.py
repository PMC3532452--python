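"""Library model, read-pair classification and per-contig evidence tracks.

An assembly is evaluated from the alignments of one short-insert paired-end
(PE) library and, optionally, one long-insert mate-pair (MP) library back to
the assembly itself.  Every aligned read with an expected mate is placed in
exactly one of four classes (proper, mis-oriented/too-distant, singleton,
mate-on-other-contig), and per-position counters plus windowed insert-size
samples are accumulated for each contig.  Downstream feature detectors work
exclusively from these tracks.

All internal coordinates are 0-based half-open; SAM input is converted on
read, GFF output on write.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional

import numpy as np

__all__ = [
    "LibraryRole",
    "Orientation",
    "LibraryProfile",
    "PairClass",
    "ReadView",
    "ContigTracks",
    "GlobalStats",
    "classify_pair",
    "build_tracks",
    "estimate_global_stats",
    "read_view_from_alignment",
    "iter_read_views",
    "window_grid",
]

DEFAULT_WINDOW = 1000
DEFAULT_STEP = 200
DEFAULT_TOLERANCE_K = 3.0
#: lower bound applied to a re-estimated insert-size standard deviation (bp)
SD_FLOOR = 1.0


class LibraryRole(str, Enum):
    PE = "PE"
    MP = "MP"


class Orientation(str, Enum):
    #: forward/reverse mates facing inward (standard paired-end)
    INNIE = "innie"
    #: reverse/forward mates facing outward (standard mate-pair)
    OUTIE = "outie"


@dataclass(frozen=True)
class LibraryProfile:
    """One sequencing library: role, rough insert statistics, orientation.

    ``insert_mean``/``insert_sd`` are the user-supplied rough estimates in bp
    (they may later be refined from properly aligned pairs, see
    :func:`estimate_global_stats`).  PE libraries default to innie
    orientation, MP libraries to outie.
    """

    role: LibraryRole
    insert_mean: float
    insert_sd: float
    orientation: Optional[Orientation] = None

    def __post_init__(self) -> None:
        if self.insert_mean <= 0:
            raise ValueError("insert_mean must be > 0")
        if self.insert_sd <= 0:
            raise ValueError("insert_sd must be > 0")
        role = LibraryRole(self.role)
        object.__setattr__(self, "role", role)
        if self.orientation is None:
            default = Orientation.INNIE if role is LibraryRole.PE else Orientation.OUTIE
            object.__setattr__(self, "orientation", default)
        else:
            object.__setattr__(self, "orientation", Orientation(self.orientation))

    def with_insert(self, mean: float, sd: float) -> "LibraryProfile":
        return LibraryProfile(self.role, mean, sd, self.orientation)


class PairClass(Enum):
    PROPER = "proper"
    #: mis-oriented, or mapped at a distance outside the tolerance window
    OUTIE = "outie"
    #: mate unmapped
    SINGLETON = "singleton"
    #: mate mapped to a different contig/scaffold
    SPANNING = "spanning"


@dataclass(frozen=True)
class ReadView:
    """Aligner-independent view of one aligned read and its mate."""

    contig: str
    pos: int                       # 0-based leftmost reference position
    ref_len: int                   # reference-consumed bases of the alignment
    is_reverse: bool
    mate_mapped: bool
    mate_contig: Optional[str] = None
    mate_pos: Optional[int] = None
    mate_is_reverse: Optional[bool] = None
    observed_fragment: Optional[int] = None   # outermost-coordinate span, bp
    is_read1: bool = True
    mapped: bool = True

    @property
    def end(self) -> int:
        return self.pos + self.ref_len

    @property
    def is_leftmost(self) -> bool:
        """True for the mate that anchors the pair (used to count pairs once)."""
        if not self.mate_mapped or self.mate_pos is None:
            return True
        if self.pos != self.mate_pos:
            return self.pos < self.mate_pos
        return self.is_read1


def _pair_orientation(read: ReadView) -> Optional[Orientation]:
    """Orientation of a same-contig pair, or None when both mates share a strand."""
    if read.is_reverse == read.mate_is_reverse:
        return None
    if read.pos < read.mate_pos:
        left_reverse = read.is_reverse
    elif read.pos > read.mate_pos:
        left_reverse = read.mate_is_reverse
    else:
        # co-located mates: the forward one is taken as leftmost
        left_reverse = False
    return Orientation.OUTIE if left_reverse else Orientation.INNIE


def classify_pair(
    read: ReadView,
    lib: LibraryProfile,
    tolerance_k: float = DEFAULT_TOLERANCE_K,
) -> PairClass:
    """Assign one of the four pair classes to a mapped read.

    SINGLETON iff the mate is unmapped; SPANNING iff the mate maps to another
    contig; OUTIE iff the pair orientation differs from the library's, or the
    observed fragment length deviates from the library mean by more than
    ``tolerance_k`` standard deviations (strict); PROPER otherwise.
    """
    if not read.mapped:
        raise ValueError("classify_pair requires a mapped read")
    if tolerance_k <= 0:
        raise ValueError("tolerance_k must be > 0")
    if not read.mate_mapped:
        return PairClass.SINGLETON
    if read.mate_contig != read.contig:
        return PairClass.SPANNING
    if _pair_orientation(read) != lib.orientation:
        return PairClass.OUTIE
    frag = read.observed_fragment
    if frag is None:
        # fall back to the mate-start distance plus one read length
        frag = abs(read.mate_pos - read.pos) + read.ref_len
    if abs(abs(frag) - lib.insert_mean) > tolerance_k * lib.insert_sd:
        return PairClass.OUTIE
    return PairClass.PROPER


def window_grid(length: int, window: int, step: int) -> list[tuple[int, int]]:
    """Sliding windows over ``[0, length)``: starts at multiples of ``step``,
    plus a final window ending at ``length`` when the tail would be uncovered."""
    if length <= window:
        return [(0, length)]
    starts = list(range(0, length - window + 1, step))
    wins = [(s, s + window) for s in starts]
    if wins[-1][1] < length:
        wins.append((length - window, length))
    return wins


class ContigTracks:
    """Per-position evidence counters and per-window insert samples for one contig.

    Arrays (all length ``length``):

    - ``read_cov``: all aligned reads (vertical coverage)
    - ``proper_cov``: reads in PROPER pairs only
    - ``span_cov``: whole fragments of PROPER pairs (horizontal coverage)
    - ``singleton_cnt`` / ``outie_cnt`` / ``spanning_cnt``: reads of that class

    ``window_inserts[i]`` collects the fragment length of every PROPER pair
    whose span covers the midpoint of window ``i`` (counted once per pair,
    from the leftmost mate).
    """

    def __init__(self, contig_id: str, length: int,
                 window: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP) -> None:
        if length <= 0:
            raise ValueError("contig length must be > 0")
        if window <= 0 or step <= 0:
            raise ValueError("window and step must be > 0")
        self.contig_id = contig_id
        self.length = length
        self.window = window
        self.step = step
        self.windows = window_grid(length, window, step)
        self.window_midpoints = np.array([(a + b) // 2 for a, b in self.windows])
        self.window_inserts: list[list[float]] = [[] for _ in self.windows]
        self.read_cov = np.zeros(length, dtype=np.int64)
        self.proper_cov = np.zeros(length, dtype=np.int64)
        self.span_cov = np.zeros(length, dtype=np.int64)
        self.singleton_cnt = np.zeros(length, dtype=np.int64)
        self.outie_cnt = np.zeros(length, dtype=np.int64)
        self.spanning_cnt = np.zeros(length, dtype=np.int64)
        self.proper_fragments: list[float] = []
        self.n_reads = 0

    _CLASS_TRACK = {
        PairClass.SINGLETON: "singleton_cnt",
        PairClass.OUTIE: "outie_cnt",
        PairClass.SPANNING: "spanning_cnt",
    }

    def _add_interval(self, arr: np.ndarray, start: int, end: int) -> None:
        arr[start:end] += 1

    def add_read(self, read: ReadView, cls: PairClass) -> None:
        if read.pos < 0 or read.end > self.length:
            raise ValueError(
                f"read at [{read.pos},{read.end}) outside contig "
                f"{self.contig_id} (length {self.length}); corrupt input"
            )
        self.n_reads += 1
        self._add_interval(self.read_cov, read.pos, read.end)
        if cls is PairClass.PROPER:
            self._add_interval(self.proper_cov, read.pos, read.end)
            if read.is_leftmost and read.observed_fragment:
                frag = abs(read.observed_fragment)
                span_end = min(read.pos + frag, self.length)
                self._add_interval(self.span_cov, read.pos, span_end)
                self.proper_fragments.append(float(frag))
                lo = np.searchsorted(self.window_midpoints, read.pos, side="left")
                hi = np.searchsorted(self.window_midpoints, span_end, side="left")
                for w in range(lo, hi):
                    self.window_inserts[w].append(float(frag))
        else:
            self._add_interval(getattr(self, self._CLASS_TRACK[cls]), read.pos, read.end)


def build_tracks(
    alignments: Iterable[ReadView],
    lib: LibraryProfile,
    contig_id: str,
    contig_length: int,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    tolerance_k: float = DEFAULT_TOLERANCE_K,
) -> ContigTracks:
    """Accumulate :class:`ContigTracks` from one contig's read views.

    The caller is responsible for excluding secondary/supplementary,
    duplicate-flagged and unmapped records (``iter_read_views`` does).
    An empty iterator yields all-zero tracks.
    """
    tracks = ContigTracks(contig_id, contig_length, window=window, step=step)
    for read in alignments:
        cls = classify_pair(read, lib, tolerance_k=tolerance_k)
        tracks.add_read(read, cls)
    return tracks


@dataclass
class GlobalStats:
    """Library-wide coverage means and (optionally refined) insert statistics."""

    mean_read_cov: float
    mean_proper_cov: float
    genome_size: int
    insert_mean: float
    insert_sd: float
    n_fragments: int = 0

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise ValueError("genome_size must be > 0")


def estimate_global_stats(
    all_tracks: Iterable[ContigTracks],
    lib: LibraryProfile,
    genome_size: int,
    refine_insert: bool = True,
    sd_floor: float = SD_FLOOR,
) -> GlobalStats:
    """Mean coverages over all assembled positions, plus refined insert stats.

    The insert mean/sd are re-estimated from PROPER fragments after discarding
    fragments outside the rough prior ± 5 sd (the user estimate is explicitly
    rough).  A degenerate refined sd is floored at ``sd_floor`` bp.
    """
    tracks = list(all_tracks)
    total_len = sum(t.length for t in tracks)
    total_reads = sum(t.n_reads for t in tracks)
    if total_len == 0 or total_reads == 0:
        raise ValueError("empty alignment")
    mean_read = sum(int(t.read_cov.sum()) for t in tracks) / total_len
    mean_proper = sum(int(t.proper_cov.sum()) for t in tracks) / total_len
    frags = np.concatenate(
        [np.asarray(t.proper_fragments, dtype=float) for t in tracks]
    ) if any(t.proper_fragments for t in tracks) else np.empty(0)
    mean_ins, sd_ins = lib.insert_mean, lib.insert_sd
    n_kept = 0
    if refine_insert and frags.size:
        keep = np.abs(frags - lib.insert_mean) <= 5.0 * lib.insert_sd
        kept = frags[keep]
        if kept.size:
            mean_ins = float(kept.mean())
            sd_ins = float(kept.std(ddof=1)) if kept.size > 1 else 0.0
            sd_ins = max(sd_ins, sd_floor)
            n_kept = int(kept.size)
    return GlobalStats(
        mean_read_cov=mean_read,
        mean_proper_cov=mean_proper,
        genome_size=int(genome_size),
        insert_mean=mean_ins,
        insert_sd=sd_ins,
        n_fragments=n_kept,
    )


# ---------------------------------------------------------------------------
# SAM/BAM adapters (pysam)
# ---------------------------------------------------------------------------

def read_view_from_alignment(aln, mapq_min: int = 0) -> Optional[ReadView]:
    """Convert a ``pysam.AlignedSegment`` to a :class:`ReadView`.

    Returns None for records that must not be counted: unmapped, secondary,
    supplementary, duplicate, QC-fail, or below the mapping-quality floor.
    """
    if (aln.is_unmapped or aln.is_secondary or aln.is_supplementary
            or aln.is_duplicate or aln.is_qcfail):
        return None
    if aln.mapping_quality < mapq_min:
        return None
    tlen = aln.template_length
    return ReadView(
        contig=aln.reference_name,
        pos=aln.reference_start,
        ref_len=aln.reference_length or len(aln.query_sequence or ""),
        is_reverse=aln.is_reverse,
        mate_mapped=aln.is_paired and not aln.mate_is_unmapped,
        mate_contig=aln.next_reference_name if aln.is_paired else None,
        mate_pos=aln.next_reference_start if aln.is_paired else None,
        mate_is_reverse=aln.mate_is_reverse if aln.is_paired else None,
        observed_fragment=abs(tlen) if tlen else None,
        is_read1=aln.is_read1,
    )


def iter_read_views(path: str, mapq_min: int = 0) -> Iterator[tuple[str, ReadView]]:
    """Stream counted read views from a coordinate-sorted SAM/BAM file,
    yielding ``(contig_id, view)`` in file order."""
    import pysam

    save = pysam.set_verbosity(0)  # silence missing-index warning for BAM
    try:
        with pysam.AlignmentFile(path, require_index=False) as fh:
            for aln in fh.fetch(until_eof=True):
                view = read_view_from_alignment(aln, mapq_min=mapq_min)
                if view is not None:
                    yield view.contig, view
    finally:
        pysam.set_verbosity(save)
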