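import numpy as np
import pytest
from scipy import stats

from oracle import levenshtein, revcomp

from concatseq.alignaf import (AmpliconPanel, PRIMARY, SECONDARY,
                               amplicon_coverage, call_hybrids, extract_af,
                               flag_to_role_orientation, map_to_panel, pileup,
                               read_alignments_tsv, role_orientation_to_flag,
                               semiglobal_align, write_alignments_tsv,
                               write_sam)
from concatseq.deconcat import FragmentRecord, deconcat_read
from concatseq.seqio import reverse_complement
from concatseq.simulate import simulate_reads


def _frag(seq, read_id="r", index=0, start=0, **kw):
    return FragmentRecord(read_id=read_id, index=index, start=start,
                          end=start + len(seq), seq=seq, **kw)


def _rand(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="module")
def panel(panel4):
    return AmpliconPanel.from_targets(panel4)


class TestFlags:
    def test_role_orientation_flag_bijection(self):
        for role in (PRIMARY, SECONDARY):
            for orientation in ("forward", "revcomp"):
                flag = role_orientation_to_flag(role, orientation)
                assert flag in (0, 16, 256, 272)
                assert flag_to_role_orientation(flag) == (role, orientation)


class TestSemiglobalAlign:
    def test_identical_sequences_align_fully(self, rng):
        s = _rand(rng, 80)
        raw = semiglobal_align(s, s)
        assert raw.score == 160
        assert (raw.query_start, raw.query_end) == (0, 80)
        assert (raw.ref_start, raw.ref_end) == (0, 80)
        assert raw.identity == 1.0

    def test_spacers_are_clipped(self, arch, rng):
        target = _rand(rng, 120)
        query = _rand(rng, 33) + target + _rand(rng, 34)
        raw = semiglobal_align(query, target)
        assert (raw.query_start, raw.query_end) == (33, 33 + 120)
        assert raw.identity == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            semiglobal_align("", "ACGT")


class TestMapToPanel:
    def test_clean_fragments_map_uniquely_with_correct_orientation(
            self, make_config, scan_params, panel):
        cfg = make_config(n_reads=60, seed=41)
        n_checked = 0
        for rec, truth in simulate_reads(cfg):
            frags, _ = deconcat_read(rec, scan_params)
            for f, unit in zip(frags, truth.units):
                records = map_to_panel(f, panel)
                assert len(records) == 1
                r = records[0]
                assert r.role == PRIMARY
                assert r.amplicon_id == unit.amplicon_id
                assert r.orientation == unit.orientation
                n_checked += 1
        assert n_checked > 200

    def test_spacer_clipping_reported(self, make_config, scan_params, panel):
        cfg = make_config(n_reads=5, seed=42)
        for rec, truth in simulate_reads(cfg):
            frags, _ = deconcat_read(rec, scan_params)
            for f, unit in zip(frags, truth.units):
                (r,) = map_to_panel(f, panel)
                assert {r.clipped5, r.clipped3} == {33, 34}
                if unit.orientation == "forward":
                    assert (r.clipped5, r.clipped3) == (33, 34)
                else:
                    assert (r.clipped5, r.clipped3) == (34, 33)

    def test_random_sequences_are_off_target(self, panel):
        local = np.random.default_rng(43)
        n_hit = 0
        for _ in range(1000):
            f = _frag(_rand(local, 187))
            n_hit += bool(map_to_panel(f, panel))
        assert n_hit == 0

    def test_revcomp_query_reported_as_revcomp(self, panel, panel4, rng):
        amp_id, target = panel4[1]
        f = _frag(reverse_complement(_rand(rng, 20) + target + _rand(rng, 20)))
        (r,) = map_to_panel(f, panel)
        assert r.amplicon_id == amp_id and r.orientation == "revcomp"


def _hybrid_fragment(panel4, rng, overlap=10, mutate_adapter=None):
    """fragA + (optional junction sequence) + chewed fragB, like a fused unit."""
    s5 = _rand(rng, 33)
    s3 = _rand(rng, 34)
    fragA = s5 + panel4[0][1] + s3
    fragB = s5 + panel4[1][1] + s3
    middle = mutate_adapter if mutate_adapter is not None else ""
    return _frag(fragA + middle + fragB[overlap:])


class TestHybrids:
    def test_fused_fragment_gets_primary_plus_secondary(self, panel, panel4, rng):
        f = _hybrid_fragment(panel4, rng)
        records = map_to_panel(f, panel)
        roles = sorted(r.role for r in records)
        assert roles == [PRIMARY, SECONDARY]
        assert {r.amplicon_id for r in records} == {panel4[0][0], panel4[1][0]}

    def test_adapterless_fusion_called_hybrid(self, panel, panel4, scan_params, rng):
        f = _hybrid_fragment(panel4, rng)
        records = map_to_panel(f, panel)
        (call,) = call_hybrids([(f, records)], scan_params, panel)
        assert call.is_hybrid and not call.rescued

    def test_five_edit_adapter_junction_is_rescued_and_split(
            self, panel, panel4, scan_params, adapter, rng):
        mutated = list(adapter.sequence)
        for p in (3, 8, 14, 20, 27):
            mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
        mutated = "".join(mutated)
        assert levenshtein(mutated, adapter.sequence) == 5
        f = _hybrid_fragment(panel4, rng, overlap=0, mutate_adapter=mutated)
        records = map_to_panel(f, panel)
        assert any(r.role == SECONDARY for r in records)
        (call,) = call_hybrids([(f, records)], scan_params, panel)
        assert call.rescued and not call.is_hybrid
        split_primaries = [r for r in call.split_records if r.role == PRIMARY]
        assert {r.amplicon_id for r in split_primaries} == \
               {panel4[0][0], panel4[1][0]}

    def test_no_hybrids_called_without_fusions(self, make_config, scan_params,
                                               panel):
        cfg = make_config(n_reads=40, seed=44)
        mapped = []
        for rec, _ in simulate_reads(cfg):
            frags, _h = deconcat_read(rec, scan_params)
            mapped.extend((f, map_to_panel(f, panel)) for f in frags)
        calls = call_hybrids(mapped, scan_params, panel)
        assert all(not c.is_hybrid for c in calls)


class TestPileup:
    def test_single_exact_alignment_covers_reference(self, panel, panel4, rng):
        amp_id, target = panel4[0]
        f = _frag(_rand(rng, 33) + target + _rand(rng, 34))
        records = map_to_panel(f, panel)
        table = pileup(records, panel)
        arr = table.counts[amp_id]
        for i, base in enumerate(target):
            assert table.depth(amp_id, i) == 1
            assert table.base_count(amp_id, i, base) == 1
        assert all(table.depth(a.id, i) == 0 for a in panel if a.id != amp_id
                   for i in range(len(a.seq)))

    def test_alt_base_counted_alongside_ref(self, panel, panel4, rng):
        amp_id, target = panel4[0]
        pos = 60
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[target[pos]]
        mutated = target[:pos] + alt + target[pos + 1:]
        frags = [_frag(_rand(rng, 33) + target + _rand(rng, 34), index=0),
                 _frag(_rand(rng, 33) + mutated + _rand(rng, 34), index=1)]
        records = [r for f in frags for r in map_to_panel(f, panel)]
        table = pileup(records, panel)
        assert table.depth(amp_id, pos) == 2
        assert table.base_count(amp_id, pos, target[pos]) == 1
        assert table.base_count(amp_id, pos, alt) == 1

    def test_deletion_counted_in_deletion_channel(self, panel, panel4, rng):
        amp_id, target = panel4[0]
        deleted = target[:50] + target[53:]  # 3-base deletion
        f = _frag(_rand(rng, 33) + deleted + _rand(rng, 34))
        records = map_to_panel(f, panel)
        assert records and records[0].amplicon_id == amp_id
        table = pileup(records, panel)
        arr = table.counts[amp_id]
        # gap placement may slide within equivalent positions, but exactly
        # three reference bases must land in the deletion channel and the
        # covered span keeps depth 1 throughout
        assert arr[:, 4].sum() == 3
        r = records[0]
        assert np.all(arr[r.ref_start:r.ref_end].sum(axis=1) == 1)

    def test_depth_conservation_against_interval_cover(self, make_config,
                                                       scan_params, panel):
        cfg = make_config(n_reads=40, sub_rate=0.006, ins_rate=0.002,
                          del_rate=0.002, seed=45)
        records = []
        for rec, _ in simulate_reads(cfg):
            frags, _h = deconcat_read(rec, scan_params)
            for f in frags:
                records.extend(map_to_panel(f, panel))
        table = pileup(records, panel)
        cover = {a.id: np.zeros(len(a.seq), dtype=int) for a in panel}
        for r in records:
            if r.role == PRIMARY:
                cover[r.amplicon_id][r.ref_start:r.ref_end] += 1
        for amp in panel:
            depths = table.counts[amp.id].sum(axis=1)
            assert np.array_equal(depths, cover[amp.id])


class TestAlleleFrequencies:
    def test_af_one_when_every_read_carries_alt(self, panel, panel4, rng):
        amp_id, target = panel4[0]
        pos, ref = 30, panel4[0][1][30]
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref]
        mutated = target[:pos] + alt + target[pos + 1:]
        frags = [_frag(_rand(rng, 33) + mutated + _rand(rng, 34), index=i)
                 for i in range(5)]
        records = [r for f in frags for r in map_to_panel(f, panel)]
        table = pileup(records, panel)
        (call,) = extract_af(table, [(amp_id, pos, ref, alt)])
        assert call.depth == 5 and call.af == 1.0

    def test_zero_depth_reported_as_undefined(self, panel, panel4):
        table = pileup([], panel)
        (call,) = extract_af(table, [(panel4[0][0], 10, panel4[0][1][10], "A"
                                      if panel4[0][1][10] != "A" else "C")])
        assert call.depth == 0 and call.af is None

    def test_out_of_bounds_position_rejected(self, panel, panel4):
        table = pileup([], panel)
        with pytest.raises(ValueError):
            extract_af(table, [(panel4[0][0], 10_000, "A", "C")])


class TestCoverage:
    def test_single_amplicon_gets_full_coverage(self, panel, panel4, rng):
        f = _frag(_rand(rng, 33) + panel4[2][1] + _rand(rng, 34))
        records = map_to_panel(f, panel)
        cov = amplicon_coverage(records)
        assert cov == {panel4[2][0]: 1.0}

    def test_fractions_sum_to_one_and_match_equimolar_pool(self, panel, panel4):
        local = np.random.default_rng(46)
        records = []
        for i in range(2000):
            amp_id, target = panel4[int(local.integers(0, 4))]
            f = _frag("".join("ACGT"[j] for j in local.integers(0, 4, 33))
                      + target
                      + "".join("ACGT"[j] for j in local.integers(0, 4, 34)),
                      read_id=f"f{i}")
            records.extend(map_to_panel(f, panel))
        cov = amplicon_coverage(records)
        assert sum(cov.values()) == pytest.approx(1.0)
        lo, hi = stats.binom.ppf([0.005, 0.995], 2000, 0.25) / 2000
        # Bonferroni over the 4 amplicons keeps the joint level ~99%
        for frac in cov.values():
            assert lo <= frac <= hi

    def test_no_alignments_rejected(self):
        with pytest.raises(ValueError):
            amplicon_coverage([])


class TestSerialization:
    def test_alignment_tsv_round_trip(self, make_config, scan_params, panel,
                                      tmp_path):
        cfg = make_config(n_reads=10, sub_rate=0.006, seed=47)
        records = []
        for rec, _ in simulate_reads(cfg):
            frags, _h = deconcat_read(rec, scan_params)
            for f in frags:
                records.extend(map_to_panel(f, panel))
        path = tmp_path / "aln.tsv"
        write_alignments_tsv(records, path)
        back = read_alignments_tsv(path)
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert a.fragment_id == b.fragment_id
            assert a.blocks == b.blocks
            assert a.sam_flag == b.sam_flag
            assert a.cigar() == b.cigar()
            assert a.aligned_seq == b.aligned_seq

    def test_sam_output_shape(self, panel, panel4, rng, tmp_path):
        f = _frag(_rand(rng, 33) + panel4[0][1] + _rand(rng, 34))
        records = map_to_panel(f, panel)
        path = tmp_path / "out.sam"
        write_sam(records, panel, path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("@HD")
        sq = [l for l in lines if l.startswith("@SQ")]
        assert len(sq) == len(panel4)
        body = [l for l in lines if not l.startswith("@")]
        assert len(body) == 1
        fields = body[0].split("\t")
        assert fields[1] in {"0", "16"}
        assert fields[5].count("S") <= 2 and "M" in fields[5]
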