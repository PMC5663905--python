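"""Sequence/annotation IO, record assembly, and the hydropathy TMD caller."""

import logging

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raftpart import seqio
from raftpart.seqio import (
    FastaParseError,
    TMDRecord,
    build_records,
    fallback_tmd_caller,
    read_annotations,
    read_fasta,
    write_fasta,
)

TRLAT = "MEEAILVPCVLGLLLLPILAMLMALCVHCHRLPGS"

seq_strategy = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=80)


class TestReadFasta:
    def test_trlat_single_record(self, tmp_path):
        f = tmp_path / "a.fasta"
        f.write_text(">trLAT\n" + TRLAT + "\n")
        recs = read_fasta(f)
        assert [(r.id, r.sequence) for r in recs] == [("trLAT", TRLAT)]

    def test_empty_file_gives_empty_list(self, tmp_path, caplog):
        f = tmp_path / "empty.fasta"
        f.write_text("")
        with caplog.at_level(logging.WARNING):
            assert read_fasta(f) == []
        assert "no records" in caplog.text

    def test_lowercase_wrapped_normalized(self, tmp_path):
        f = tmp_path / "a.fasta"
        f.write_text(">x desc here\nmeea\nILVp\n")
        (rec,) = read_fasta(f)
        assert rec.sequence == "MEEAILVP"
        assert rec.id == "x"
        assert rec.description == "desc here"

    def test_sequence_before_header_names_line(self, tmp_path):
        f = tmp_path / "bad.fasta"
        f.write_text("\nACGT\n>x\nACGT\n")
        with pytest.raises(FastaParseError, match=r"bad\.fasta:2"):
            read_fasta(f)

    @settings(deadline=None, max_examples=25)
    @given(seqs=st.lists(seq_strategy, min_size=1, max_size=5, unique=True))
    def test_write_read_round_trip(self, tmp_path_factory, seqs):
        path = tmp_path_factory.mktemp("fa") / "rt.fasta"
        records = [(f"s{i}", s) for i, s in enumerate(seqs)]
        write_fasta(records, path)
        back = read_fasta(path)
        assert [(r.id, r.sequence) for r in back] == records


class TestAnnotations:
    def _write(self, tmp_path, body):
        f = tmp_path / "annot.tsv"
        f.write_text("id\ttmd_start\ttmd_end\torientation\tcompartment\n" + body)
        return f

    def test_typed_row(self, tmp_path):
        df = read_annotations(self._write(tmp_path, "trLAT\t5\t27\texo_to_cyto\tPM\n"))
        row = df.iloc[0]
        assert (row["id"], row["tmd_start"], row["tmd_end"]) == ("trLAT", 5, 27)
        assert row["compartment"] == "PM"
        assert row["n_palm"] is None

    def test_header_only_is_empty(self, tmp_path):
        assert read_annotations(self._write(tmp_path, "")).empty

    def test_duplicate_ids_rejected(self, tmp_path):
        f = self._write(tmp_path, "a\t1\t5\texo_to_cyto\tPM\na\t2\t6\texo_to_cyto\tPM\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_annotations(f)

    def test_non_integer_coordinate_names_row(self, tmp_path):
        f = self._write(tmp_path, "a\tfive\t9\texo_to_cyto\tPM\n")
        with pytest.raises(ValueError, match="'a'"):
            read_annotations(f)

    def test_reversed_span_rejected(self, tmp_path):
        f = self._write(tmp_path, "a\t9\t5\texo_to_cyto\tPM\n")
        with pytest.raises(ValueError, match="tmd_end < tmd_start"):
            read_annotations(f)

    def test_unknown_orientation_rejected(self, tmp_path):
        f = self._write(tmp_path, "a\t1\t5\tsideways\tPM\n")
        with pytest.raises(ValueError, match="orientation"):
            read_annotations(f)

    def test_missing_orientation_defaults_exo_to_cyto(self, tmp_path):
        f = tmp_path / "annot.tsv"
        f.write_text("id\ttmd_start\ttmd_end\na\t1\t5\n")
        assert read_annotations(f).iloc[0]["orientation"] == "exo_to_cyto"


class TestTMDRecord:
    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ValueError, match="non-standard"):
            TMDRecord(id="x", sequence="AAXAA", tmd_start=1, tmd_end=5)

    def test_span_must_fit_sequence(self):
        with pytest.raises(ValueError, match="span"):
            TMDRecord(id="x", sequence="AAAAA", tmd_start=2, tmd_end=9)

    def test_cyto_terminus_follows_orientation(self):
        kw = dict(id="x", sequence="A" * 10, tmd_start=3, tmd_end=8)
        assert TMDRecord(orientation="exo_to_cyto", **kw).cyto_terminus == 8
        assert TMDRecord(orientation="cyto_to_exo", **kw).cyto_terminus == 3


class TestBuildRecords:
    def test_counts_and_skips(self, tmp_path, caplog):
        seqs = [("a", "A" * 30), ("b", "L" * 30), ("c", "V" * 30)]
        f = tmp_path / "annot.tsv"
        f.write_text(
            "id\ttmd_start\ttmd_end\torientation\n"
            "a\t2\t20\texo_to_cyto\nb\t5\t25\texo_to_cyto\n"
        )
        with caplog.at_level(logging.INFO):
            recs = build_records(seqs, read_annotations(f))
        assert [r.id for r in recs] == ["a", "b"]
        assert "'c'" in caplog.text and "skipped" in caplog.text

    def test_row_order_irrelevant(self, tmp_path):
        seqs = [("a", "A" * 30), ("b", "L" * 30)]
        fwd = tmp_path / "f.tsv"
        rev = tmp_path / "r.tsv"
        fwd.write_text("id\ttmd_start\ttmd_end\torientation\na\t2\t20\texo_to_cyto\nb\t5\t25\texo_to_cyto\n")
        rev.write_text("id\ttmd_start\ttmd_end\torientation\nb\t5\t25\texo_to_cyto\na\t2\t20\texo_to_cyto\n")
        assert set(build_records(seqs, read_annotations(fwd))) == set(
            build_records(seqs, read_annotations(rev))
        )

    def test_annotation_without_sequence_errors(self, tmp_path):
        f = tmp_path / "annot.tsv"
        f.write_text("id\ttmd_start\ttmd_end\torientation\nghost\t1\t5\texo_to_cyto\n")
        with pytest.raises(ValueError, match="ghost"):
            build_records([("a", "A" * 10)], read_annotations(f))

    def test_trlat_tmd_contains_cytoplasmic_cysteines(self, trlat):
        # the palmitoylated Cys pair sits at/just past the cytoplasmic TMD end
        assert trlat.tmd_seq.count("C") >= 1
        cyto_region = trlat.sequence[trlat.tmd_end - 8 : trlat.tmd_end + 7]
        assert cyto_region.count("C") == 2


class TestFallbackCaller:
    def test_uniform_leucine_called(self):
        span = fallback_tmd_caller("L" * 30, window=19, threshold=1.6)
        assert span is not None
        start, end = span
        assert 1 <= start <= end <= 30

    def test_poly_asp_not_called(self):
        assert fallback_tmd_caller("D" * 30, window=19, threshold=1.6) is None

    def test_short_sequence_returns_none(self, caplog):
        with caplog.at_level(logging.WARNING):
            assert fallback_tmd_caller("LLLL", window=19) is None

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            fallback_tmd_caller("L" * 30, window=10)

    def test_trlat_span_overlaps_annotation_and_matches_oracle(self, trlat, kd_scale):
        window, threshold = 19, 1.6
        called = fallback_tmd_caller(trlat.sequence, window=window, threshold=threshold)
        assert called is not None
        # independent oracle: windowed means computed directly
        vals = [kd_scale[aa] for aa in trlat.sequence]
        half = window // 2
        qualifying = [
            c for c in range(half + 1, len(vals) - half + 1)
            if sum(vals[c - 1 - half : c + half]) / window > threshold
        ]
        runs, cur = [], [qualifying[0]]
        for prev, nxt in zip(qualifying, qualifying[1:]):
            if nxt == prev + 1:
                cur.append(nxt)
            else:
                runs.append(cur)
                cur = [nxt]
        runs.append(cur)
        best = max(runs, key=len)
        assert called == (best[0], best[-1])
        # overlaps the annotated hydrophobic core
        assert called[0] <= trlat.tmd_end and called[1] >= trlat.tmd_start

    def test_deterministic(self):
        seq = "MEEA" + "L" * 25 + "HRLPGS"
        assert fallback_tmd_caller(seq) == fallback_tmd_caller(seq)
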