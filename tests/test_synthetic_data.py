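import collections

import numpy as np
import pytest

from frcurve import (
    BenchmarkConfig,
    EventRequest,
    EventType,
    LibraryProfile,
    LibraryRole,
    PairClass,
    apply_misassembly_events,
    classify_pair,
    generate_reference,
    liftover_alignments,
    plant_tandem_duplication,
    run_benchmark,
    simulate_pairs,
)
from frcurve.synthetic_data import records_to_read_views, revcomp

PE = LibraryProfile(LibraryRole.PE, 300.0, 30.0)
MP = LibraryProfile(LibraryRole.MP, 3000.0, 300.0)


class TestGenerateReference:
    def test_seed_determinism(self):
        a = generate_reference(1000, 0.5, seed=7)
        b = generate_reference(1000, 0.5, seed=7)
        assert a == b and len(a) == 1000

    def test_gc_one_boundary(self):
        seq = generate_reference(500, gc=1.0, seed=0)
        assert set(seq) <= {"G", "C"}

    def test_planted_repeat_family(self):
        seq = generate_reference(
            20_000, repeat_spec={"n_repeats": 1, "repeat_len": 500, "n_copies": 3},
            seed=3)
        # locate the repeat unit via its first occurrence and count copies
        counts = collections.Counter()
        for i in range(0, len(seq) - 500 + 1):
            counts[seq[i:i + 500]] += 1
        assert max(counts.values()) >= 3

    def test_repeat_mass_overflow_rejected(self):
        with pytest.raises(ValueError):
            generate_reference(
                1000, repeat_spec={"n_repeats": 2, "repeat_len": 400, "n_copies": 2})

    def test_plant_tandem_duplication(self):
        ref = generate_reference(5000, seed=1)
        planted = plant_tandem_duplication(ref, 2000, 300)
        assert len(planted) == len(ref)
        assert planted[1700:2000] == planted[2000:2300]


class TestApplyEvents:
    def test_no_events_identity(self):
        ref = generate_reference(3000, seed=2)
        asm = apply_misassembly_events(ref, [], seed=0)
        assert asm.contigs == [("contig_1", ref)]
        assert asm.truth.intervals == []
        assert (asm.liftover.pos == np.arange(3000)).all()
        assert not asm.liftover.flip.any()

    def test_inversion_is_reverse_complement(self):
        ref = generate_reference(4000, seed=2)
        asm = apply_misassembly_events(
            ref, [EventRequest(EventType.INVERSION, 1000, 2000)], seed=0)
        seq = asm.contigs[0][1]
        assert seq[1000:2000] == revcomp(ref[1000:2000])
        assert seq[:1000] == ref[:1000] and seq[2000:] == ref[2000:]
        assert asm.liftover.flip[1000:2000].all()

    def test_compression_length_bookkeeping(self):
        ref = plant_tandem_duplication(generate_reference(6000, seed=4), 3000, 500)
        asm = apply_misassembly_events(
            ref, [EventRequest(EventType.COMPRESSION, 3000, 3500)], seed=0)
        assert len(asm.contigs[0][1]) == 6000 - 500
        # the deleted copy maps onto the retained copy
        assert (asm.liftover.pos[3000:3500] == asm.liftover.pos[2500:3000]).all()

    def test_expansion_and_insertion_lengths(self):
        ref = generate_reference(6000, seed=5)
        asm = apply_misassembly_events(
            ref, [EventRequest(EventType.EXPANSION, 1000, 1400),
                  EventRequest(EventType.CHIMERIC_INSERTION, 4000, length=250)],
            seed=0)
        assert len(asm.contigs[0][1]) == 6000 + 400 + 250

    def test_fragmentation_splits_contig(self):
        ref = generate_reference(5000, seed=6)
        asm = apply_misassembly_events(
            ref, [EventRequest(EventType.FRAGMENTATION, 2000)], seed=0)
        assert asm.lengths == {"contig_1": 2000, "contig_2": 3000}
        assert asm.contigs[0][1] + asm.contigs[1][1] == ref

    def test_relocation_moves_segment(self):
        ref = generate_reference(8000, seed=7)
        asm = apply_misassembly_events(
            ref, [EventRequest(EventType.RELOCATION, 2000, 2500, target=4000)],
            seed=0)
        seq = asm.contigs[0][1]
        assert len(seq) == 8000
        assert seq[2000:3500] == ref[2500:4000]
        assert seq[3500:4000] == ref[2000:2500]

    def test_overlapping_events_rejected(self):
        ref = generate_reference(5000, seed=8)
        with pytest.raises(ValueError, match="overlap"):
            apply_misassembly_events(
                ref, [EventRequest(EventType.INVERSION, 1000, 2000),
                      EventRequest(EventType.DELETION, 1500, 1800)], seed=0)


class TestSimulatePairs:
    def test_exact_pair_count(self):
        ref = generate_reference(100_000, seed=9)
        pairs = simulate_pairs(ref, PE, coverage=40, read_len=100, seed=0)
        assert len(pairs) == 20_000  # floor(40 * 100000 / 200)

    def test_error_free_reads_are_reference_substrings(self):
        ref = generate_reference(20_000, seed=10)
        for p in simulate_pairs(ref, PE, 2, 100, err_rate=0.0, seed=1)[:200]:
            assert p.left_seq == ref[p.left_pos:p.left_pos + 100]
            assert p.right_seq == ref[p.right_pos:p.right_pos + 100]

    def test_fragment_sample_mean(self):
        ref = generate_reference(100_000, seed=11)
        pairs = simulate_pairs(ref, MP, 40, 100, seed=2)
        frs = np.array([p.fragment for p in pairs])
        assert abs(frs.mean() - 3000) < 3 * 300 / np.sqrt(len(frs))

    def test_insert_longer_than_reference_rejected(self):
        with pytest.raises(ValueError):
            simulate_pairs("ACGT" * 100, MP, 10, 100, seed=0)

    def test_orientation_follows_library(self):
        ref = generate_reference(20_000, seed=12)
        pe = simulate_pairs(ref, PE, 1, 100, seed=3)[0]
        mp = simulate_pairs(ref, MP, 1, 100, seed=3)[0]
        assert (pe.left_reverse, pe.right_reverse) == (False, True)   # innie
        assert (mp.left_reverse, mp.right_reverse) == (True, False)   # outie


class TestLiftoverAlignments:
    def _classify_all(self, records, contigs, lib):
        views = records_to_read_views(records, contigs)
        return [classify_pair(v, lib) for vs in views.values() for v in vs
                if v.mate_mapped or True]

    def test_identity_liftover_gives_proper_pairs(self):
        ref = generate_reference(30_000, seed=13)
        asm = apply_misassembly_events(ref, [], seed=0)
        pairs = simulate_pairs(ref, PE, 10, 100, err_rate=0.0, seed=4)
        recs = liftover_alignments(pairs, asm.liftover, asm.contigs)
        classes = self._classify_all(recs, asm.contigs, PE)
        frac_proper = sum(c is PairClass.PROPER for c in classes) / len(classes)
        # only fragments drawn beyond +/-3 sd are (correctly) not proper
        assert frac_proper > 0.99
        assert not any(c is PairClass.SINGLETON or c is PairClass.SPANNING
                       for c in classes)

    def test_compression_shortens_straddling_fragments(self):
        """Mates flanking a collapsed repeat copy map closer together: the
        observed fragment equals the drawn one minus the repeat length."""
        rep = 500
        s, e = 10_000, 10_500
        ref = plant_tandem_duplication(generate_reference(30_000, seed=14), s, rep)
        asm = apply_misassembly_events(
            ref, [EventRequest(EventType.COMPRESSION, s, e)], seed=0)
        pairs = simulate_pairs(ref, MP, 10, 100, err_rate=0.0, seed=5)
        recs = {r.qname + ("/1" if r.flag & 0x40 else "/2"): r
                for r in liftover_alignments(pairs, asm.liftover, asm.contigs)}
        checked = 0
        for p in pairs:
            if p.left_pos + p.read_len <= s - rep and p.right_pos >= e:
                r = recs.get(f"sim_{p.pair_id}/1")
                assert r is not None and not r.flag & 0x4
                assert abs(r.tlen) == p.fragment - rep
                checked += 1
        assert checked > 20

    def test_inversion_flips_one_mate_to_outie(self):
        s, e = 8_000, 11_000
        ref = generate_reference(30_000, seed=15)
        asm = apply_misassembly_events(
            ref, [EventRequest(EventType.INVERSION, s, e)], seed=0)
        pairs = simulate_pairs(ref, MP, 10, 100, err_rate=0.0, seed=6)
        recs = liftover_alignments(pairs, asm.liftover, asm.contigs)
        checked = 0
        rec_by_pair = collections.defaultdict(list)
        for r in recs:
            rec_by_pair[r.qname].append(r)
        def fully_in(pos, rl):
            return s <= pos and pos + rl <= e

        def fully_out(pos, rl):
            return pos + rl <= s or pos >= e

        for p in pairs:
            rl = p.read_len
            one_in = ((fully_in(p.left_pos, rl) and fully_out(p.right_pos, rl))
                      or (fully_out(p.left_pos, rl) and fully_in(p.right_pos, rl)))
            if not one_in:
                continue
            rs = rec_by_pair[f"sim_{p.pair_id}"]
            mapped = [r for r in rs if not r.flag & 0x4]
            if len(mapped) != 2:
                continue
            views_p = records_to_read_views(mapped, asm.contigs)["contig_1"]
            for v in views_p:
                assert classify_pair(v, MP) is PairClass.OUTIE
            checked += 1
        assert checked > 20

    def test_deleted_origin_reads_unmapped(self):
        ref = generate_reference(30_000, seed=16)
        s, e = 12_000, 13_000
        asm = apply_misassembly_events(
            ref, [EventRequest(EventType.DELETION, s, e)], seed=0)
        pairs = simulate_pairs(ref, PE, 30, 100, err_rate=0.0, seed=7)
        recs = liftover_alignments(pairs, asm.liftover, asm.contigs)
        by_pair = collections.defaultdict(list)
        for r in recs:
            by_pair[r.qname].append(r)
        checked = 0
        for p in pairs:
            if s <= p.left_pos and p.left_pos + p.read_len <= e:
                # left read's origin was deleted: any surviving record for it
                # must carry the unmapped flag (pair dropped if both unmapped)
                for r in by_pair.get(f"sim_{p.pair_id}", []):
                    if r.flag & 0x40:
                        assert r.flag & 0x4
                        checked += 1
        assert checked > 5


class TestRunBenchmark:
    CFG = BenchmarkConfig(genome_length=20_000, pe_coverage=20, mp_coverage=8,
                          events=(EventRequest(EventType.INVERSION, 6000, 8500),))

    def test_same_seed_same_results(self):
        a = run_benchmark(self.CFG, seed=5)
        b = run_benchmark(self.CFG, seed=5)
        assert a.features == b.features
        assert a.senspec == b.senspec
        assert a.reference == b.reference

    def test_event_free_run_has_no_pair_anomaly_features(self, clean_report):
        bad = {t for t in (r.type.value for r in clean_report.features)
               if t.startswith(("HIGH_OUTIE", "HIGH_SPAN", "HIGH_SINGLE"))}
        assert bad == set()

    def test_sam_round_trip_matches_in_memory_tracks(self, tmp_path):
        """Writing SAM and re-reading through pysam reproduces the same
        per-contig read views the pipeline used in memory."""
        from frcurve.core_model import build_tracks, iter_read_views
        from frcurve.synthetic_data import (
            liftover_alignments as lift, simulate_pairs as sim, write_sam)

        ref = generate_reference(15_000, seed=20)
        asm = apply_misassembly_events(
            ref, [EventRequest(EventType.FRAGMENTATION, 9000)], seed=0)
        pairs = sim(ref, PE, 8, 100, err_rate=0.01, seed=8)
        recs = lift(pairs, asm.liftover, asm.contigs)
        path = tmp_path / "t.sam"
        write_sam(recs, asm.contigs, str(path))
        views_mem = records_to_read_views(recs, asm.contigs)
        views_sam = collections.defaultdict(list)
        for cid, v in iter_read_views(str(path)):
            views_sam[cid].append(v)
        for cid, n in asm.lengths.items():
            t_mem = build_tracks(views_mem[cid], PE, cid, n)
            t_sam = build_tracks(views_sam[cid], PE, cid, n)
            assert (t_mem.read_cov == t_sam.read_cov).all()
            assert (t_mem.proper_cov == t_sam.proper_cov).all()
            assert (t_mem.outie_cnt == t_sam.outie_cnt).all()
            assert (t_mem.span_cov == t_sam.span_cov).all()
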