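"""Synthetic benchmark: reference genomes, typed mis-assemblies with an
exact truth ledger, simulated PE/MP pairs, and liftover alignments.

The simulator replaces a real aligner: reads are drawn from the *reference*
and placed on the mis-assembled contigs through the exact coordinate map the
corruption induced.  This makes every downstream expectation checkable —
the truth intervals are known by construction, fragments spanning a
collapsed repeat really are shorter by the repeat length, mates with one end
inside an inversion really are mis-oriented — without downloading data or
running an external mapper.

Event types and the signal they plant:

- INVERSION: segment reverse-complemented in place; pairs straddling a
  breakpoint become mis-oriented (same-strand).
- COMPRESSION: the second copy of a tandem duplication is dropped; reads
  from it pile onto the first copy and spanning fragments shorten by the
  repeat length (negative CE).
- EXPANSION: a segment is duplicated; reads map only to the first copy,
  fragments across the event lengthen (positive CE) and the extra copy has
  no coverage.
- CHIMERIC_INSERTION: foreign sequence inserted; zero coverage on the body.
- DELETION: reference sequence dropped; reads from it go unmapped.
- RELOCATION: a segment is moved downstream; pairs across the three new
  junctions map too distant.
- FRAGMENTATION: the contig is split; pairs across the cut land on
  different contigs.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .core_model import (
    LibraryProfile,
    LibraryRole,
    Orientation,
    ReadView,
    build_tracks,
    estimate_global_stats,
)
from .curves import assembly_summary, compute_frcurve, per_feature_curves, summaries_from_regions
from .feature_detection import FeatureRegion, Thresholds, annotate_contig
from .validation import TruthSet, sensitivity_specificity

__all__ = [
    "EventType",
    "EventRequest",
    "MisassemblyEvent",
    "AssemblyResult",
    "Liftover",
    "SimulatedPair",
    "AlignmentRecord",
    "generate_reference",
    "plant_tandem_duplication",
    "apply_misassembly_events",
    "simulate_pairs",
    "liftover_alignments",
    "write_sam",
    "records_to_read_views",
    "BenchmarkConfig",
    "BenchmarkReport",
    "standard_events",
    "run_benchmark",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class EventType(str, Enum):
    INVERSION = "INVERSION"
    RELOCATION = "RELOCATION"
    COMPRESSION = "COMPRESSION"
    EXPANSION = "EXPANSION"
    CHIMERIC_INSERTION = "CHIMERIC_INSERTION"
    DELETION = "DELETION"
    FRAGMENTATION = "FRAGMENTATION"


#: event types whose truth interval is the affected body (vs. breakpoint flanks)
_BODY_EVENTS = {EventType.INVERSION, EventType.EXPANSION,
                EventType.CHIMERIC_INSERTION}


@dataclass(frozen=True)
class EventRequest:
    """A requested corruption, in reference coordinates.

    - INVERSION/DELETION/EXPANSION: act on ``[start, end)``.
    - COMPRESSION: delete ``[start, end)`` and map it onto the preceding
      tandem copy ``[start-L, start)`` (the reference must carry that copy;
      see :func:`plant_tandem_duplication`).
    - CHIMERIC_INSERTION: insert ``length`` random bases at ``start``.
    - RELOCATION: move ``[start, end)`` to just before ``target`` (>= end).
    - FRAGMENTATION: split the contig at ``start``.
    """

    type: EventType
    start: int
    end: int = -1
    target: Optional[int] = None
    length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.end == -1:
            object.__setattr__(self, "end", self.start)
        t = EventType(self.type)
        object.__setattr__(self, "type", t)
        if t in (EventType.CHIMERIC_INSERTION, EventType.FRAGMENTATION):
            if self.end != self.start:
                raise ValueError(f"{t.value} is a point event")
            if t is EventType.CHIMERIC_INSERTION and not self.length:
                raise ValueError("CHIMERIC_INSERTION needs a length")
        elif self.end <= self.start:
            raise ValueError(f"{t.value} needs end > start")
        if t is EventType.RELOCATION and (self.target is None or self.target < self.end):
            raise ValueError("RELOCATION needs target >= end")

    @property
    def ref_span(self) -> tuple[int, int]:
        """Reference interval this event occupies (used for overlap checks)."""
        if self.type is EventType.RELOCATION:
            return (self.start, self.target)
        return (self.start, self.end)


@dataclass(frozen=True)
class MisassemblyEvent:
    """A realised corruption with its truth interval(s) on the assembly."""

    type: EventType
    ref_interval: tuple[int, int]
    asm_interval: tuple[str, int, int]
    truth_intervals: tuple[tuple[str, int, int], ...] = ()


@dataclass
class Liftover:
    """Total map reference position -> (contig index, position, strand flip);
    contig index -1 marks positions with no assembly image (deleted bases)."""

    contig: np.ndarray
    pos: np.ndarray
    flip: np.ndarray


@dataclass
class AssemblyResult:
    contigs: list[tuple[str, str]]      # (contig_id, sequence)
    truth: TruthSet
    liftover: Liftover
    events: list[MisassemblyEvent]

    @property
    def lengths(self) -> dict[str, int]:
        return {cid: len(seq) for cid, seq in self.contigs}


def generate_reference(
    length: int,
    gc: float = 0.5,
    repeat_spec: Optional[dict] = None,
    seed: int = 0,
) -> str:
    """I.i.d. random genome at the given GC with optional planted exact
    repeat families (``{"n_repeats": f, "repeat_len": l, "n_copies": c}``)."""
    if length <= 0:
        raise ValueError("length must be > 0")
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must be in [0,1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=length, p=p)
    if repeat_spec:
        n_fam = int(repeat_spec.get("n_repeats", 1))
        rep_len = int(repeat_spec["repeat_len"])
        n_copies = int(repeat_spec.get("n_copies", 2))
        if n_fam * rep_len * n_copies > length:
            raise ValueError("repeat mass exceeds genome length")
        slots = length // (n_fam * n_copies)
        if slots < rep_len:
            raise ValueError("repeat mass exceeds genome length")
        k = 0
        for fam in range(n_fam):
            unit = rng.choice(bases, size=rep_len, p=p)
            for _ in range(n_copies):
                start = k * slots + int(rng.integers(0, slots - rep_len + 1))
                seq[start:start + rep_len] = unit
                k += 1
    return "".join(seq)


def plant_tandem_duplication(reference: str, start: int, length: int) -> str:
    """Overwrite ``[start, start+length)`` with a copy of the preceding
    ``length`` bases, creating an exact tandem duplication."""
    if start - length < 0 or start + length > len(reference):
        raise ValueError("tandem duplication does not fit")
    return reference[:start] + reference[start - length:start] + reference[start + length:]


class _AssemblyBuilder:
    def __init__(self, ref_len: int):
        self.lift = Liftover(
            contig=np.full(ref_len, -1, dtype=np.int32),
            pos=np.full(ref_len, -1, dtype=np.int64),
            flip=np.zeros(ref_len, dtype=bool),
        )
        self.seqs: list[str] = []
        self.pieces: list[str] = []
        self.off = 0
        self.ci = 0
        self.truths: list[tuple[int, int, int, str]] = []  # contig-idx coords, unclipped

    def emit_identity(self, ref: str, a: int, b: int) -> None:
        if b <= a:
            return
        self.pieces.append(ref[a:b])
        self.lift.contig[a:b] = self.ci
        self.lift.pos[a:b] = self.off + np.arange(b - a)
        self.off += b - a

    def emit_inverted(self, ref: str, a: int, b: int) -> None:
        self.pieces.append(revcomp(ref[a:b]))
        self.lift.contig[a:b] = self.ci
        # ref position p maps to off + (b-1-p); strand flipped
        self.lift.pos[a:b] = self.off + (b - 1 - np.arange(a, b))
        self.lift.flip[a:b] = True
        self.off += b - a

    def emit_unmapped_copy(self, seq: str) -> None:
        self.pieces.append(seq)
        self.off += len(seq)

    def close_contig(self) -> None:
        self.seqs.append("".join(self.pieces))
        self.pieces = []
        self.off = 0
        self.ci += 1

    def add_truth(self, start: int, end: int, etype: EventType) -> None:
        self.truths.append((self.ci, start, end, etype.value))


def apply_misassembly_events(
    reference: str,
    events: Sequence[EventRequest],
    seed: int = 0,
    truth_flank: int = 500,
) -> AssemblyResult:
    """Realise the requested events on the reference.

    Truth intervals mark the affected assembly span: the event body for
    INVERSION/EXPANSION/CHIMERIC_INSERTION, and each junction +/- one
    ``truth_flank`` for breakpoint-type events (paired reads are the
    detection instrument, so their signal concentrates within about one
    fragment length of a junction).  The liftover is total on unaffected
    reference positions.
    """
    L = len(reference)
    rng = np.random.default_rng(seed)
    ordered = sorted(events, key=lambda e: e.ref_span)
    cursor = 0
    for ev in ordered:
        a, b = ev.ref_span
        if a < cursor:
            raise ValueError(
                f"event {ev.type.value} at {a} overlaps the previous event "
                f"(reference occupied through {cursor})")
        if b > L:
            raise ValueError(f"event {ev.type.value} extends past the reference")
        cursor = max(cursor, b if b > a else a)
    bld = _AssemblyBuilder(L)
    realised: list[tuple[EventRequest, int, int]] = []  # with first-truth index range
    cursor = 0
    for ev in ordered:
        bld.emit_identity(reference, cursor, ev.start)
        t0 = len(bld.truths)
        if ev.type is EventType.INVERSION:
            body0 = bld.off
            bld.emit_inverted(reference, ev.start, ev.end)
            bld.add_truth(body0, bld.off, ev.type)
            cursor = ev.end
        elif ev.type is EventType.DELETION:
            bld.add_truth(bld.off - truth_flank, bld.off + truth_flank, ev.type)
            cursor = ev.end
        elif ev.type is EventType.COMPRESSION:
            rep_len = ev.end - ev.start
            src = slice(ev.start - rep_len, ev.start)
            if ev.start - rep_len < 0:
                raise ValueError("COMPRESSION needs a preceding tandem copy")
            if np.any(bld.lift.contig[src] < 0):
                raise ValueError("COMPRESSION source copy is not in the assembly")
            bld.lift.contig[ev.start:ev.end] = bld.lift.contig[src]
            bld.lift.pos[ev.start:ev.end] = bld.lift.pos[src]
            bld.lift.flip[ev.start:ev.end] = bld.lift.flip[src]
            bld.add_truth(bld.off - truth_flank, bld.off + truth_flank, ev.type)
            cursor = ev.end
        elif ev.type is EventType.EXPANSION:
            body0 = bld.off
            bld.emit_identity(reference, ev.start, ev.end)
            bld.emit_unmapped_copy(reference[ev.start:ev.end])
            bld.add_truth(body0, bld.off, ev.type)
            cursor = ev.end
        elif ev.type is EventType.CHIMERIC_INSERTION:
            body0 = bld.off
            foreign = "".join(np.random.default_rng(rng.integers(2**31)).choice(
                np.array(list("ACGT")), size=ev.length))
            bld.emit_unmapped_copy(foreign)
            bld.add_truth(body0, bld.off, ev.type)
            cursor = ev.start
        elif ev.type is EventType.RELOCATION:
            j0 = bld.off
            bld.emit_identity(reference, ev.end, ev.target)
            j1 = bld.off
            bld.emit_identity(reference, ev.start, ev.end)
            j2 = bld.off
            for j in (j0, j1, j2):
                bld.add_truth(j - truth_flank, j + truth_flank, ev.type)
            cursor = ev.target
        elif ev.type is EventType.FRAGMENTATION:
            end_len = bld.off
            bld.add_truth(max(0, end_len - truth_flank), end_len, ev.type)
            bld.close_contig()
            bld.add_truth(0, truth_flank, ev.type)
            cursor = ev.start
        realised.append((ev, t0, len(bld.truths)))
    bld.emit_identity(reference, cursor, L)
    bld.close_contig()

    names = [f"contig_{i + 1}" for i in range(len(bld.seqs))]
    lengths = {n: len(s) for n, s in zip(names, bld.seqs)}
    intervals = []
    for ci, a, b, etype in bld.truths:
        n = lengths[names[ci]]
        a, b = max(0, a), min(n, b)
        if b > a:
            intervals.append((names[ci], a, b, etype))
    truth = TruthSet(intervals=intervals, assembly_lengths=dict(lengths))
    out_events = []
    for ev, t0, t1 in realised:
        ivs = []
        for ci, a, b, etype in bld.truths[t0:t1]:
            n = lengths[names[ci]]
            a, b = max(0, a), min(n, b)
            if b > a:
                ivs.append((names[ci], a, b))
        span = ivs[0] if ivs else (names[0], 0, 0)
        if len(ivs) > 1 and all(iv[0] == ivs[0][0] for iv in ivs):
            span = (ivs[0][0], min(iv[1] for iv in ivs), max(iv[2] for iv in ivs))
        out_events.append(MisassemblyEvent(
            type=ev.type,
            ref_interval=(ev.start, ev.end),
            asm_interval=span,
            truth_intervals=tuple(ivs),
        ))
    contigs = list(zip(names, bld.seqs))
    return AssemblyResult(contigs=contigs, truth=truth, liftover=bld.lift,
                          events=out_events)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedPair:
    """One fragment and its two reads, in reference coordinates.

    ``left_*``/``right_*`` refer to reference order; sequences are stored as
    the reference-forward strand (with substitution errors applied).  For an
    innie library the left read is forward and the right reverse; an outie
    library is the opposite.
    """

    pair_id: int
    left_pos: int
    right_pos: int
    read_len: int
    fragment: int
    left_seq: str
    right_seq: str
    left_reverse: bool
    right_reverse: bool


def simulate_pairs(
    reference: str,
    lib: LibraryProfile,
    coverage: float,
    read_len: int = 100,
    err_rate: float = 0.0,
    seed: int = 0,
) -> list[SimulatedPair]:
    """Uniformly placed pairs at ``floor(coverage * L / (2*read_len))`` count.

    Fragment lengths are Gaussian ``N(insert_mean, insert_sd)`` truncated
    below at ``2*read_len``; per-base substitution errors at ``err_rate``.
    """
    L = len(reference)
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if read_len >= lib.insert_mean:
        raise ValueError("read_len must be < insert_mean")
    if lib.insert_mean >= L:
        raise ValueError("insert_mean must be smaller than the reference")
    rng = np.random.default_rng(seed)
    n = int(coverage * L / (2 * read_len))
    frags = np.round(rng.normal(lib.insert_mean, lib.insert_sd, n)).astype(np.int64)
    frags = np.clip(frags, 2 * read_len, L)
    starts = np.floor(rng.random(n) * (L - frags + 1)).astype(np.int64)
    innie = lib.orientation is Orientation.INNIE
    pairs: list[SimulatedPair] = []
    err_counts = (rng.binomial(read_len, err_rate, size=(n, 2))
                  if err_rate > 0 else np.zeros((n, 2), dtype=int))
    bases = "ACGT"
    for i in range(n):
        s = int(starts[i])
        f = int(frags[i])
        lpos, rpos = s, s + f - read_len
        lseq = reference[lpos:lpos + read_len]
        rseq = reference[rpos:rpos + read_len]
        seqs = [lseq, rseq]
        for j in range(2):
            k = int(err_counts[i, j])
            if k:
                chars = list(seqs[j])
                for p in rng.integers(0, read_len, size=k):
                    old = chars[p]
                    chars[p] = bases[(bases.index(old) + 1 + int(rng.integers(3))) % 4] \
                        if old in bases else "A"
                seqs[j] = "".join(chars)
        pairs.append(SimulatedPair(
            pair_id=i, left_pos=lpos, right_pos=rpos, read_len=read_len,
            fragment=f, left_seq=seqs[0], right_seq=seqs[1],
            left_reverse=not innie, right_reverse=innie,
        ))
    return pairs


# ---------------------------------------------------------------------------
# liftover "alignment"
# ---------------------------------------------------------------------------

@dataclass
class AlignmentRecord:
    qname: str
    flag: int
    ref_id: int            # contig index, -1 unmapped-without-placement
    pos: int               # 0-based
    mapq: int
    cigar: str
    rnext_id: int
    pnext: int
    tlen: int
    seq: str

    def sam_line(self, names: Sequence[str]) -> str:
        rname = names[self.ref_id] if self.ref_id >= 0 else "*"
        rnext = ("=" if self.rnext_id == self.ref_id else names[self.rnext_id]) \
            if self.rnext_id >= 0 else "*"
        return "\t".join([
            self.qname, str(self.flag), rname, str(self.pos + 1),
            str(self.mapq), self.cigar, rnext, str(self.pnext + 1),
            str(self.tlen), self.seq, "I" * len(self.seq),
        ])


def _map_read(lift: Liftover, p: int, rl: int, tol: int):
    """Map reference interval [p, p+rl) through the liftover.

    Returns (contig, asm_start, asm_end, flip, run_a, run_b) for the best
    end-anchored collinear run, or None if the read straddles a breakpoint
    by more than ``tol`` bases (or originates in deleted sequence)."""
    c = lift.contig[p:p + rl]
    q = lift.pos[p:p + rl]
    f = lift.flip[p:p + rl]
    idx = np.arange(rl)
    if c[0] >= 0:
        d = -1 if f[0] else 1
        ok = (c == c[0]) & (f == f[0]) & (q == q[0] + d * idx)
        k_pre = rl if ok.all() else int(np.argmin(ok))
    else:
        k_pre = 0
    if c[-1] >= 0:
        d = -1 if f[-1] else 1
        ok = (c == c[-1]) & (f == f[-1]) & (q == q[-1] - d * (rl - 1 - idx))
        okr = ok[::-1]
        k_suf = rl if okr.all() else int(np.argmin(okr))
    else:
        k_suf = 0
    if max(k_pre, k_suf) < rl - tol:
        return None
    if k_pre >= k_suf:
        a, b = 0, k_pre
    else:
        a, b = rl - k_suf, rl
    flip = bool(f[a])
    if flip:
        asm_start = int(q[b - 1])
        asm_end = int(q[a]) + 1
    else:
        asm_start = int(q[a])
        asm_end = int(q[b - 1]) + 1
    return int(c[a]), asm_start, asm_end, flip, a, b


def _cigar_and_seq(rl: int, a: int, b: int, flip: bool, seq: str) -> tuple[str, str]:
    stored = revcomp(seq) if flip else seq
    if flip:
        lc, rc = rl - b, a
    else:
        lc, rc = a, rl - b
    parts = []
    if lc:
        parts.append(f"{lc}S")
    parts.append(f"{b - a}M")
    if rc:
        parts.append(f"{rc}S")
    return "".join(parts), stored


def liftover_alignments(
    pairs: Sequence[SimulatedPair],
    liftover: Liftover,
    contigs: Sequence[tuple[str, str]],
    breakpoint_tolerance: int = 20,
    mapq: int = 60,
    qname_prefix: str = "sim",
) -> list[AlignmentRecord]:
    """Place simulated pairs on the assembly via the exact coordinate map.

    Reads from deleted/foreign sequence go unmapped (their mates become
    singleton evidence); reads inside an inversion flip strand; reads
    overhanging an event junction by more than ``breakpoint_tolerance`` bases
    go unmapped (a real aligner would clip or drop them).  Output records are
    coordinate-sorted with correct FLAG, RNAME, POS and TLEN (outermost span,
    leftmost mate positive).
    """
    records: list[AlignmentRecord] = []
    for pair in pairs:
        rl = pair.read_len
        maps = []
        for p, seq, orig_rev in (
            (pair.left_pos, pair.left_seq, pair.left_reverse),
            (pair.right_pos, pair.right_seq, pair.right_reverse),
        ):
            m = _map_read(liftover, p, rl, breakpoint_tolerance)
            if m is None:
                maps.append(None)
            else:
                ci, a0, a1, flip, ra, rb = m
                cigar, stored = _cigar_and_seq(rl, ra, rb, flip, seq)
                maps.append((ci, a0, a1, orig_rev != flip, cigar, stored))
        if maps[0] is None and maps[1] is None:
            continue
        name = f"{qname_prefix}_{pair.pair_id}"
        recs = []
        for j in (0, 1):
            me, other = maps[j], maps[1 - j]
            flag = 0x1 | (0x40 if j == 0 else 0x80)
            seq_raw = pair.left_seq if j == 0 else pair.right_seq
            if me is None:
                oc, oa0, _, orev, _, _ = other
                flag |= 0x4 | (0x20 if orev else 0)
                recs.append(AlignmentRecord(name, flag, oc, oa0, 0, "*",
                                            oc, oa0, 0, seq_raw))
                continue
            ci, a0, a1, rev, cigar, stored = me
            if rev:
                flag |= 0x10
            if other is None:
                flag |= 0x8
                recs.append(AlignmentRecord(name, flag, ci, a0, mapq, cigar,
                                            ci, a0, 0, stored))
                continue
            oci, oa0, oa1, orev, _, _ = other
            if orev:
                flag |= 0x20
            if oci == ci:
                span = max(a1, oa1) - min(a0, oa0)
                if a0 < oa0 or (a0 == oa0 and j == 0):
                    tlen = span
                else:
                    tlen = -span
            else:
                tlen = 0
            recs.append(AlignmentRecord(name, flag, ci, a0, mapq, cigar,
                                        oci, oa0, tlen, stored))
        records.extend(recs)
    records.sort(key=lambda r: (r.ref_id if r.ref_id >= 0 else r.rnext_id,
                                r.pos, r.qname, r.flag))
    return records


def write_sam(records: Sequence[AlignmentRecord],
              contigs: Sequence[tuple[str, str]], path: str) -> None:
    names = [c[0] for c in contigs]
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for cid, seq in contigs:
            fh.write(f"@SQ\tSN:{cid}\tLN:{len(seq)}\n")
        for r in records:
            fh.write(r.sam_line(names) + "\n")


def records_to_read_views(
    records: Sequence[AlignmentRecord],
    contigs: Sequence[tuple[str, str]],
) -> dict[str, list[ReadView]]:
    """In-memory equivalent of writing SAM and re-reading it with pysam."""
    names = [c[0] for c in contigs]
    out: dict[str, list[ReadView]] = {c[0]: [] for c in contigs}
    for r in records:
        if r.flag & 0x4:
            continue
        ref_len = sum(int(n) for n, op in _iter_cigar(r.cigar) if op in "MDN=X")
        out[names[r.ref_id]].append(ReadView(
            contig=names[r.ref_id],
            pos=r.pos,
            ref_len=ref_len,
            is_reverse=bool(r.flag & 0x10),
            mate_mapped=not (r.flag & 0x8),
            mate_contig=names[r.rnext_id] if r.rnext_id >= 0 else None,
            mate_pos=r.pnext,
            mate_is_reverse=bool(r.flag & 0x20),
            observed_fragment=abs(r.tlen) if r.tlen else None,
            is_read1=bool(r.flag & 0x40),
        ))
    return out


def _iter_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield num, ch
            num = ""


# ---------------------------------------------------------------------------
# benchmark driver
# ---------------------------------------------------------------------------

def standard_events(genome_length: int) -> list[EventRequest]:
    """The standard corruption layout, scaled to the genome length.

    At 100 kb: two inversions (2.5 kb and 2 kb), one 500 bp tandem-repeat
    collapse, one 1 kb chimeric insertion, one 2 kb relocation moved 8 kb
    downstream, and one fragmentation."""
    L = genome_length

    def at(frac: float) -> int:
        return int(frac * L)

    return [
        EventRequest(EventType.INVERSION, at(0.10), at(0.125)),
        EventRequest(EventType.COMPRESSION, at(0.30), at(0.305)),
        EventRequest(EventType.CHIMERIC_INSERTION, at(0.45), length=max(1, at(0.01))),
        EventRequest(EventType.INVERSION, at(0.60), at(0.62)),
        EventRequest(EventType.RELOCATION, at(0.70), at(0.72), target=at(0.80)),
        EventRequest(EventType.FRAGMENTATION, at(0.90)),
    ]


@dataclass(frozen=True)
class BenchmarkConfig:
    """Study conditions for the synthetic benchmark.

    Defaults are the standard conditions: a 100 kb genome, an 80x innie PE
    library (insert 300 +/- 30, 100 bp reads) and a 20x outie MP library
    (insert 3000 +/- 300), 1% substitution errors, and the standard event
    layout.  ``truth_flank`` for breakpoint events defaults to the PE insert
    mean; validation ``slack`` and the contig-edge exclusion default to the
    largest library insert mean.
    """

    genome_length: int = 100_000
    gc: float = 0.5
    pe: LibraryProfile = LibraryProfile(LibraryRole.PE, 300.0, 30.0)
    mp: Optional[LibraryProfile] = LibraryProfile(LibraryRole.MP, 3000.0, 300.0)
    pe_coverage: float = 80.0
    mp_coverage: float = 20.0
    read_len: int = 100
    err_rate: float = 0.01
    events: tuple[EventRequest, ...] = None  # None -> standard layout
    thresholds: Thresholds = Thresholds()
    window: int = 1000
    step: int = 200
    tolerance_k: float = 3.0
    breakpoint_tolerance: int = 20
    truth_flank: Optional[int] = None
    slack: Optional[int] = None
    edge_exclude: Optional[int] = None

    def resolved_events(self) -> list[EventRequest]:
        if self.events is None:
            return standard_events(self.genome_length)
        return list(self.events)

    @property
    def max_insert(self) -> int:
        m = self.pe.insert_mean
        if self.mp is not None:
            m = max(m, self.mp.insert_mean)
        return int(m)

    @property
    def truth_flank_(self) -> int:
        return int(self.pe.insert_mean) if self.truth_flank is None else self.truth_flank

    @property
    def slack_(self) -> int:
        return self.max_insert if self.slack is None else self.slack

    @property
    def edge_exclude_(self) -> int:
        return self.max_insert if self.edge_exclude is None else self.edge_exclude


@dataclass
class BenchmarkReport:
    config: BenchmarkConfig
    seed: int
    reference: str
    assembly: AssemblyResult
    features: list[FeatureRegion]
    stats_pe: object
    stats_mp: object
    global_curve: list
    per_feature: dict
    summary: dict
    senspec: dict
    flagged_fraction_non_edge: float


def _flagged_fraction(features: Sequence[FeatureRegion],
                      lengths: dict[str, int], edge: int) -> float:
    total = flagged = 0
    masks = {}
    for cid, n in lengths.items():
        keep = np.zeros(n, dtype=bool)
        if n > 2 * edge:
            keep[edge:n - edge] = True
        masks[cid] = (keep, np.zeros(n, dtype=bool))
        total += int(keep.sum())
    for r in features:
        masks[r.contig_id][1][r.start:r.end] = True
    for keep, fl in masks.values():
        flagged += int((keep & fl).sum())
    return flagged / total if total else 0.0


def run_benchmark(
    config: BenchmarkConfig = BenchmarkConfig(),
    seed: int = 0,
    outdir: Optional[str] = None,
) -> BenchmarkReport:
    """Full pipeline on synthetic data: genome -> corrupted assembly ->
    simulated alignments -> features -> curves -> sensitivity/specificity.

    Deterministic per seed.  When ``outdir`` is given, writes the reference
    and contig FASTA, truth and feature GFF3, per-library SAM, curve files
    and a JSON report."""
    from . import gff_io

    rng = np.random.default_rng(seed)
    s_ref, s_events, s_pe, s_mp = (int(x) for x in rng.integers(0, 2**31 - 1, 4))

    events = config.resolved_events()
    reference = generate_reference(config.genome_length, config.gc, seed=s_ref)
    for ev in events:
        if ev.type is EventType.COMPRESSION:
            reference = plant_tandem_duplication(reference, ev.start, ev.end - ev.start)
    asm = apply_misassembly_events(reference, events, seed=s_events,
                                   truth_flank=config.truth_flank_)

    libs: list[tuple[LibraryProfile, float, int]] = [(config.pe, config.pe_coverage, s_pe)]
    if config.mp is not None:
        libs.append((config.mp, config.mp_coverage, s_mp))
    views_by_lib = []
    records_by_lib = []
    for lib, cov, s in libs:
        pairs = simulate_pairs(reference, lib, cov, config.read_len,
                               config.err_rate, seed=s)
        recs = liftover_alignments(pairs, asm.liftover, asm.contigs,
                                   breakpoint_tolerance=config.breakpoint_tolerance,
                                   qname_prefix=f"sim{lib.role.value}")
        records_by_lib.append(recs)
        views_by_lib.append(records_to_read_views(recs, asm.contigs))

    lengths = asm.lengths
    tracks_by_lib = []
    stats_by_lib = []
    for (lib, _, _), views in zip(libs, views_by_lib):
        tr = {cid: build_tracks(views[cid], lib, cid, lengths[cid],
                                window=config.window, step=config.step,
                                tolerance_k=config.tolerance_k)
              for cid in lengths}
        tracks_by_lib.append(tr)
        stats_by_lib.append(estimate_global_stats(tr.values(), lib,
                                                  config.genome_length))

    features: list[FeatureRegion] = []
    for cid in lengths:
        kwargs = {}
        if config.mp is not None:
            kwargs = dict(tracks_mp=tracks_by_lib[1][cid],
                          stats_mp=stats_by_lib[1], lib_mp=config.mp)
        features.extend(annotate_contig(
            tracks_by_lib[0][cid], stats_by_lib[0], config.pe,
            th=config.thresholds, **kwargs))
    features.sort(key=lambda r: (r.contig_id, r.start, r.end, r.type.value))

    global_curve = compute_frcurve(
        summaries_from_regions(features, lengths), config.genome_length)
    per_feat = per_feature_curves(features, lengths, config.genome_length)
    summary = assembly_summary(list(lengths.values()), config.genome_length)
    senspec = sensitivity_specificity(features, asm.truth, slack=config.slack_)
    flagged = _flagged_fraction(features, lengths, config.edge_exclude_)

    report = BenchmarkReport(
        config=config, seed=seed, reference=reference, assembly=asm,
        features=features, stats_pe=stats_by_lib[0],
        stats_mp=stats_by_lib[1] if config.mp is not None else None,
        global_curve=global_curve, per_feature=per_feat, summary=summary,
        senspec=senspec, flagged_fraction_non_edge=flagged,
    )
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        gff_io.write_fasta([("reference", reference)],
                           os.path.join(outdir, "reference.fasta"))
        gff_io.write_fasta(asm.contigs, os.path.join(outdir, "contigs.fasta"))
        gff_io.write_truth_gff(asm.truth, os.path.join(outdir, "truth.gff3"))
        for (lib, _, _), recs in zip(libs, records_by_lib):
            write_sam(recs, asm.contigs,
                      os.path.join(outdir, f"{lib.role.value.lower()}.sam"))
        gff_io.write_feature_gff(features, os.path.join(outdir, "features.gff3"),
                                 contig_lengths=lengths)
        gff_io.write_curves(global_curve, per_feat,
                            os.path.join(outdir, "frc"))
        rep = {
            "seed": seed,
            "summary": summary,
            "sens": senspec["sens"], "spec": senspec["spec"],
            "tp": senspec["tp"], "fp": senspec["fp"],
            "tn": senspec["tn"], "fn": senspec["fn"],
            "flagged_fraction_non_edge": flagged,
            "n_features": len(features),
            "pe_insert_refined": [stats_by_lib[0].insert_mean,
                                  stats_by_lib[0].insert_sd],
        }
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(rep, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report
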