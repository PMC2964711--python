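"""Motif nomenclature parsing, table reading and variant calling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtn1a.hvs_io import (
    AlphabetError,
    Haplotype,
    MotifParseError,
    MutationCall,
    PositionRangeError,
    SchemaError,
    apply_mutations,
    call_variants,
    format_motif,
    parse_motif,
    parse_token,
    read_haplotype_table,
)
from mtn1a.reference import TRANSITION_PARTNER, MT_LENGTH


class TestParseMotif:
    def test_basal_motif_with_transversion(self, ref):
        calls = parse_motif("147G-172-223-248", "hvs1", ref)
        assert [c.position for c in calls] == [16147, 16172, 16223, 16248]
        assert calls[0].event == "transversion" and calls[0].derived == "G"
        assert all(c.event == "transition" for c in calls[1:])

    def test_insertion_token(self, ref):
        calls = parse_motif("147A-172-189-193iC-223-248-320-355", "hvs1", ref)
        assert len(calls) == 8
        ins = [c for c in calls if c.event == "insertion"]
        assert len(ins) == 1 and ins[0].position == 16193 and ins[0].derived == "C"

    def test_double_insertion(self, ref):
        (call,) = parse_motif("193iCC", "hvs1", ref)
        assert call.derived == "CC"

    def test_empty_motif(self, ref):
        assert parse_motif("", "hvs2", ref) == []
        assert parse_motif("   ", "hvs1", ref) == []

    def test_deletion_and_back_mutation(self, ref):
        (d,) = parse_motif("249d", "hvs1", ref)
        assert d.event == "deletion" and d.position == 16249
        (b,) = parse_motif("@172", "hvs1", ref)
        assert b.is_back_mutation and b.event == "transition"

    def test_hvs2_token_not_offset(self, ref):
        (c,) = parse_motif("152", "hvs2", ref)
        assert c.position == 152

    @pytest.mark.parametrize("token", ["abc", "12X3", "147Q", ""])
    def test_bad_tokens(self, ref, token):
        with pytest.raises(MotifParseError):
            parse_token(token, "hvs1", ref)

    def test_out_of_window(self, ref):
        with pytest.raises(PositionRangeError):
            parse_motif("700", "hvs1", ref)  # 16700 beyond the molecule
        with pytest.raises(PositionRangeError):
            parse_motif("600", "hvs2", ref)  # outside the control region half


class TestFormatMotif:
    def test_inverse_of_parse(self, ref):
        calls = parse_motif("147A-172", "hvs1", ref)
        assert format_motif(calls, "hvs1") == "147A-172"
        assert format_motif([], "hvs1") == ""

    def test_out_of_window_call_rejected(self, ref):
        (c,) = parse_motif("152", "hvs2", ref)
        with pytest.raises(PositionRangeError):
            format_motif([c], "hvs1", ref)

    def test_round_trip_on_entire_fixture(self, ref):
        import pandas as pd
        from importlib import resources

        with resources.as_file(
            resources.files("mtn1a.data") / "n1a_haplotypes.tsv"
        ) as p:
            df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
        for segment, column in (("hvs1", "hvs1_motif"), ("hvs2", "hvs2_motif")):
            for motif in df[column]:
                calls = parse_motif(motif, segment, ref)
                assert format_motif(calls, segment) == motif

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(data=st.data())
    def test_round_trip_random_calls(self, ref, data):
        positions = data.draw(st.lists(
            st.integers(16024, 16383), min_size=0, max_size=8, unique=True))
        calls = []
        for pos in positions:
            ref_base = ref.base(pos)
            kind = data.draw(st.sampled_from(["ts", "tv", "del", "ins"]))
            if kind == "ts":
                calls.append(MutationCall(pos, ref_base, "transition",
                                          TRANSITION_PARTNER[ref_base]))
            elif kind == "tv":
                alt = data.draw(st.sampled_from(sorted(
                    set("ACGT") - {ref_base, TRANSITION_PARTNER[ref_base]})))
                calls.append(MutationCall(pos, ref_base, "transversion", alt))
            elif kind == "del":
                calls.append(MutationCall(pos, ref_base, "deletion"))
            else:
                ins = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=3))
                calls.append(MutationCall(pos, ref_base, "insertion", ins))
        motif = format_motif(calls, "hvs1")
        assert parse_motif(motif, "hvs1", ref) == sorted(
            calls, key=lambda c: (c.position, c.event == "insertion", c.derived))


class TestReadTable:
    def test_fixture_dimensions(self, fixture_haps):
        assert len(fixture_haps) == 115
        assert sum(h.count for h in fixture_haps) == 166

    def test_known_row(self, fixture_haps):
        rows = [h for h in fixture_haps
                if h.population == "Kazakhstan" and h.count == 5]
        assert len(rows) == 1
        assert format_motif(rows[0].hvs1, "hvs1") == "147A-172-189-223-248-320-355"
        assert rows[0].recorded_haplogroup == "N1a1a1a"

    def test_implicit_hvs2_calls_added(self, fixture_haps):
        typed = [h for h in fixture_haps if h.hvs2_typed]
        assert typed, "fixture has HVS-II rows"
        for h in typed:
            positions = {c.position for c in h.hvs2}
            assert {73, 263} <= positions
        untyped = [h for h in fixture_haps if not h.hvs2_typed]
        assert all(not h.hvs2 for h in untyped)

    def test_header_only_file(self, ref, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("haplogroup\thvs1_motif\thvs2_motif\tn\tpopulation\tregion\tsource\n")
        assert read_haplotype_table(p, ref) == []

    def test_missing_column(self, ref, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("haplogroup\thvs1_motif\n")
        with pytest.raises(SchemaError, match="missing columns"):
            read_haplotype_table(p, ref)

    def test_nonpositive_count(self, ref, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("haplogroup\thvs1_motif\thvs2_motif\tn\tpopulation\tregion\tsource\n"
                     "N1a\t147G\t\t0\tX\tY\tZ\n")
        with pytest.raises(ValueError, match=">= 1"):
            read_haplotype_table(p, ref)


class TestCallVariants:
    def test_identity(self, ref):
        assert call_variants(ref.sequence, ref) == []

    def test_single_substitution(self, ref):
        pos = 8000
        alt = TRANSITION_PARTNER[ref.base(pos)]
        seq = ref.sequence[: pos - 1] + alt + ref.sequence[pos:]
        (call,) = call_variants(seq, ref)
        assert call.position == pos and call.event == "transition"
        assert call.derived == alt

    def test_excluded_site_never_called(self, ref):
        pos = 16519
        alt = TRANSITION_PARTNER[ref.base(pos)]
        seq = ref.sequence[: pos - 1] + alt + ref.sequence[pos:]
        assert call_variants(seq, ref) == []

    def test_n_bases_not_scored(self, ref):
        seq = "N" * 10 + ref.sequence[10:]
        assert call_variants(seq, ref) == []

    def test_alphabet_error(self, ref):
        with pytest.raises(AlphabetError):
            call_variants("X" + ref.sequence[1:], ref)

    def test_deletion_right_shifted_in_homopolymer(self, ref):
        # delete the first C of a homopolymer run; the call must sit at the
        # 3' end of the run
        seq = ref.sequence
        run_start = seq.find("CCCC", 5000)
        run_end = run_start
        while seq[run_end + 1] == "C":
            run_end += 1
        mutated = seq[:run_start] + seq[run_start + 1 :]
        calls = call_variants(mutated, ref)
        dels = [c for c in calls if c.event == "deletion"]
        assert len(dels) == 1 and dels[0].position == run_end + 1

    def test_polyc_tract_insertion_dropped(self, ref):
        # extra C inside the HVS-II poly-C tract is length variation: ignored
        seq = ref.sequence[:305] + "C" + ref.sequence[305:]
        assert call_variants(seq, ref) == []

    def test_planted_set_round_trip(self, ref):
        """apply_mutations then call_variants is the identity on planted
        substitution sets avoiding excluded sites (1,000 seeded cases)."""
        rng = np.random.default_rng(606)
        legal = [p for p in range(1, MT_LENGTH + 1)
                 if p not in ref.excluded_sites and not ref.in_polyc(p)]
        legal = np.array(legal)
        for _ in range(1000):
            k = int(rng.integers(0, 12))
            positions = rng.choice(legal, size=k, replace=False)
            calls = []
            for pos in sorted(int(p) for p in positions):
                base = ref.base(pos)
                alt = (TRANSITION_PARTNER[base] if rng.random() < 0.8
                       else sorted(set("ACGT") - {base, TRANSITION_PARTNER[base]})[
                           int(rng.integers(2))])
                event = ("transition" if alt == TRANSITION_PARTNER[base]
                         else "transversion")
                calls.append(MutationCall(pos, base, event, alt))
            seq = apply_mutations(ref.sequence, calls)
            assert call_variants(seq, ref) == calls


class TestHaplotype:
    def test_duplicate_positions_rejected(self, ref):
        calls = parse_motif("147A-147G", "hvs1", ref)
        with pytest.raises(ValueError, match="duplicate"):
            Haplotype(id="x", hvs1=calls, hvs2=[])

    def test_insertion_not_a_duplicate(self, ref):
        calls = parse_motif("193-193iC", "hvs1", ref)
        h = Haplotype(id="x", hvs1=calls, hvs2=[])
        assert len(h.hvs1) == 2
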