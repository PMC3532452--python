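"""Independent brute-force oracles used by the test suite.

Everything here recomputes results with naive per-base / per-prefix loops,
deliberately sharing no code with the library implementations.
"""

from __future__ import annotations

import numpy as np


def brute_force_pair_class(read, lib, tolerance_k=3.0) -> str:
    """Naive re-derivation of the four-way pair classification."""
    if not read.mate_mapped:
        return "singleton"
    if read.mate_contig != read.contig:
        return "spanning"
    # orientation of the pair: strand of the leftmost mate decides
    if read.is_reverse == read.mate_is_reverse:
        return "outie"
    if read.pos < read.mate_pos:
        left_rev = read.is_reverse
    elif read.pos > read.mate_pos:
        left_rev = read.mate_is_reverse
    else:
        left_rev = False
    orient = "outie" if left_rev else "innie"
    if orient != lib.orientation.value:
        return "outie"
    frag = read.observed_fragment
    if frag is None:
        frag = abs(read.mate_pos - read.pos) + read.ref_len
    if abs(abs(frag) - lib.insert_mean) > tolerance_k * lib.insert_sd:
        return "outie"
    return "proper"


def brute_force_tracks(reads, lib, length, windows, tolerance_k=3.0):
    """Per-base loop over all reads; returns dict of counter lists plus
    per-window fragment multisets (windows given as (start, end) pairs)."""
    counters = {k: [0] * length for k in
                ("read_cov", "proper_cov", "span_cov",
                 "singleton_cnt", "outie_cnt", "spanning_cnt")}
    win_inserts = [[] for _ in windows]
    mids = [(a + b) // 2 for a, b in windows]
    for r in reads:
        cls = brute_force_pair_class(r, lib, tolerance_k)
        for p in range(r.pos, r.pos + r.ref_len):
            counters["read_cov"][p] += 1
            if cls == "proper":
                counters["proper_cov"][p] += 1
            elif cls == "singleton":
                counters["singleton_cnt"][p] += 1
            elif cls == "outie":
                counters["outie_cnt"][p] += 1
            else:
                counters["spanning_cnt"][p] += 1
        if cls == "proper" and r.is_leftmost and r.observed_fragment:
            frag = abs(r.observed_fragment)
            span_end = min(r.pos + frag, length)
            for p in range(r.pos, span_end):
                counters["span_cov"][p] += 1
            for w, m in enumerate(mids):
                if r.pos <= m < span_end:
                    win_inserts[w].append(float(frag))
    return counters, win_inserts


def brute_force_frcurve(summaries, genome_size, taus):
    """All-prefix enumeration: for each tau, the best (longest) prefix of the
    size-sorted contig list whose feature sum stays within tau."""
    ordered = sorted(summaries, key=lambda s: (-s.length, s.contig_id))
    points = []
    for tau in taus:
        best_len = 0
        feats = 0
        total = 0
        for s in ordered:
            feats += s.feature_count
            if feats > tau:
                break
            total += s.length
            best_len = total
        points.append(min(1.0, best_len / genome_size))
    return points


def brute_force_merge(intervals, merge_gap, min_region):
    """Union-then-filter with a plain position set."""
    if not intervals:
        return []
    lo = min(a for a, _ in intervals)
    hi = max(b for _, b in intervals)
    occupied = set()
    for a, b in intervals:
        occupied.update(range(a, b))
    # merge runs whose gap < merge_gap
    merged = []
    cur = None
    for p in range(lo, hi + 1):
        if p in occupied:
            if cur is None:
                cur = [p, p + 1]
            elif p - cur[1] < merge_gap:
                cur[1] = p + 1
            else:
                merged.append(tuple(cur))
                cur = [p, p + 1]
    if cur:
        merged.append(tuple(cur))
    return [(a, b) for a, b in merged if b - a >= min_region]


def brute_force_senspec(features, truth_intervals, lengths, slack=0):
    """Per-position confusion matrix by explicit looping."""
    tp = fp = tn = fn = 0
    for cid, n in lengths.items():
        in_truth = [False] * n
        for tcid, a, b, _ in truth_intervals:
            if tcid == cid:
                for p in range(max(0, a - slack), min(n, b + slack)):
                    in_truth[p] = True
        in_feat = [False] * n
        for r in features:
            if r.contig_id == cid:
                for p in range(r.start, r.end):
                    in_feat[p] = True
        for p in range(n):
            if in_truth[p] and in_feat[p]:
                tp += 1
            elif in_truth[p]:
                fn += 1
            elif in_feat[p]:
                fp += 1
            else:
                tn += 1
    return tp, fp, tn, fn


def random_read_views(rng, contig, length, n_reads, lib):
    """Random but structurally valid read views for oracle comparisons."""
    from frcurve import ReadView

    reads = []
    for i in range(n_reads):
        rl = int(rng.integers(20, 101))
        pos = int(rng.integers(0, length - rl + 1))
        kind = rng.random()
        if kind < 0.1:  # mate unmapped
            reads.append(ReadView(contig, pos, rl, bool(rng.integers(2)),
                                  False))
            continue
        if kind < 0.2:  # mate on another contig
            reads.append(ReadView(contig, pos, rl, bool(rng.integers(2)),
                                  True, "other", int(rng.integers(0, 1000)),
                                  bool(rng.integers(2)), None))
            continue
        frag = int(rng.integers(2 * rl, max(2 * rl + 1, int(2.0 * lib.insert_mean))))
        mate_pos = min(max(0, pos + frag - rl), length - rl)
        reads.append(ReadView(
            contig, pos, rl, bool(rng.integers(2)), True, contig, mate_pos,
            bool(rng.integers(2)), frag, is_read1=bool(rng.integers(2))))
    return reads
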