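"""Tests of ABIF and reference parsing/serialisation."""

import io
import struct
import zipfile

import numpy as np
import pytest

from sangerbatch import errors, trace_io
from sangerbatch.trace_io import (
    Chromatogram,
    ReferenceRecord,
    read_ab1,
    read_references,
    read_trace_archive,
    write_ab1,
)

from conftest import random_chromatogram


def serialize(chrom: Chromatogram) -> bytes:
    buf = io.BytesIO()
    write_ab1(chrom, buf)
    return buf.getvalue()


def small_chromatogram() -> Chromatogram:
    return Chromatogram(
        source_name="tiny",
        channel_order="GATC",
        channels={b: np.arange(100) * (i + 1) for i, b in enumerate("ACGT")},
        peak_positions=np.arange(10) * 10 + 3,
        bases="ACGTNACGTA",
        qualities=np.arange(10) + 30,
    )


class TestAbifRoundTrip:
    def test_round_trip_identity(self):
        c = small_chromatogram()
        assert read_ab1(serialize(c), "tiny") == c

    def test_round_trip_random_fixtures(self, rng):
        for _ in range(25):
            c = random_chromatogram(rng)
            assert read_ab1(serialize(c), c.source_name) == c

    def test_empty_base_trace(self):
        c = Chromatogram("empty", "GATC", {b: np.zeros(100, dtype=int) for b in "ACGT"},
                         np.array([], dtype=int), "", np.array([], dtype=int))
        parsed = read_ab1(serialize(c), "empty")
        assert parsed.bases == "" and parsed.signal_length == 100

    def test_quality_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="qualities"):
            Chromatogram("bad", "GATC", {b: np.zeros(50, dtype=int) for b in "ACGT"},
                         np.array([5]), "A", np.array([94]))


class TestAbifReader:
    def test_bad_magic_is_format_error(self):
        with pytest.raises(errors.TraceFormatError, match="sample1"):
            read_ab1(b"PDF%" + b"\x00" * 100, "sample1")

    def test_missing_tag_is_tag_error(self):
        blob = bytearray(serialize(small_chromatogram()))
        # corrupt every PBAS directory entry name
        idx = 0
        while True:
            idx = blob.find(b"PBAS", idx)
            if idx < 0:
                break
            blob[idx : idx + 4] = b"XXXX"
            idx += 4
        with pytest.raises(errors.TraceTagError, match="PBAS"):
            read_ab1(bytes(blob), "tiny")

    def test_pbas_ploc_length_mismatch_is_integrity_error(self):
        c = small_chromatogram()
        blob = serialize(c)
        # hand-build a file whose PCON is one byte short by truncating counts:
        # easier to corrupt the directory count of PLOC entries via struct surgery
        # on the num_elements field of every PLOC entry.
        raw = bytearray(blob)
        idx = 0
        while True:
            idx = raw.find(b"PLOC", idx)
            if idx < 0:
                break
            # directory entry: name(4) number(4) type(2) size(2) count(4)
            count = struct.unpack_from(">i", raw, idx + 12)[0]
            struct.pack_into(">i", raw, idx + 12, count - 1)
            idx += 4
        with pytest.raises(errors.TraceIntegrityError):
            read_ab1(bytes(raw), "tiny")

    def test_channel_letter_mapping_follows_fwo(self):
        """channels[letter] must come from the DATA tag at FWO_'s index of
        that letter; verified against an independent struct-level decode."""
        c = small_chromatogram()
        blob = serialize(c)
        # independent hand decode of the directory
        tdir = struct.unpack_from(">4sihhiiii", blob, 6)
        entries = {}
        for i in range(tdir[4]):
            e = struct.unpack_from(">4sihhiiii", blob, tdir[6] + 28 * i)
            entries[(e[0].decode(), e[1])] = e
        fwo = struct.pack(">i", entries[("FWO_", 1)][6]).decode()
        assert fwo == "GATC"
        parsed = read_ab1(blob, "tiny")
        for i, letter in enumerate(fwo):
            e = entries[("DATA", 9 + i)]
            data = np.frombuffer(blob[e[6] : e[6] + e[5]], dtype=">i2")
            assert np.array_equal(parsed.channels[letter], data)

    def test_biopython_reads_our_files(self):
        """Interoperability: Biopython's abi parser agrees on sequence,
        qualities and peak locations."""
        from Bio import SeqIO

        c = small_chromatogram()
        rec = SeqIO.read(io.BytesIO(serialize(c)), "abi")
        assert str(rec.seq) == c.bases
        assert rec.letter_annotations["phred_quality"] == list(c.qualities)
        raw = rec.annotations["abif_raw"]
        assert list(raw["PLOC2"]) == list(c.peak_positions)

    def test_non_acgt_bases_normalised_to_n(self):
        c = Chromatogram("amb", "GATC", {b: np.zeros(50, dtype=int) for b in "ACGT"},
                         np.array([5, 15, 25]), "AYR", np.array([20, 20, 20]))
        assert c.bases == "ANN"


class TestReferences:
    def test_fasta_full_sequence_cds(self):
        refs = read_references(">refA\nACGTAC\n>refB\nGGGTTTA\n")
        assert [(r.ref_id, r.sequence, r.cds_start, r.cds_end) for r in refs] == [
            ("refA", "ACGTAC", 0, 6),
            ("refB", "GGGTTTA", 0, 7),
        ]

    def test_csv_table(self):
        refs = read_references("id,sequence\nr1,ACGT\n")
        assert refs[0] == ReferenceRecord("r1", "ACGT", 0, 4, "table")

    def test_xlsx_same_schema(self, tmp_path):
        import pandas as pd

        f = tmp_path / "refs.xlsx"
        pd.DataFrame({"id": ["rX"], "sequence": ["ACGTACGT"]}).to_excel(f, index=False)
        refs = read_references(f.read_bytes())
        assert refs[0].ref_id == "rX" and refs[0].sequence == "ACGTACGT"

    def test_format_stability_fasta_vs_table(self):
        fasta = read_references(">a\nACGTGA\n>b\nTTTACG\n")
        table = read_references("id,sequence\na,ACGTGA\nb,TTTACG\n")
        for f, t in zip(fasta, table):
            assert (f.ref_id, f.sequence, f.cds_start, f.cds_end) == (
                t.ref_id, t.sequence, t.cds_start, t.cds_end)

    def test_genbank_cds_coordinates(self):
        gb = (
            "LOCUS       test1                 15 bp    DNA     linear   UNA 01-JAN-2000\n"
            "FEATURES             Location/Qualifiers\n"
            "     CDS             4..12\n"
            "ORIGIN\n"
            "        1 atgaaatttg ggtaa\n"
            "//\n"
        )
        (ref,) = read_references(gb)
        # 1-based inclusive 4..12 is 0-based half-open [3, 12)
        assert (ref.cds_start, ref.cds_end) == (3, 12)
        assert ref.source_format == "genbank"

    def test_genbank_without_cds_falls_back_to_full_sequence(self, caplog):
        gb = (
            "LOCUS       nocds                 6 bp    DNA     linear   UNA 01-JAN-2000\n"
            "ORIGIN\n"
            "        1 atgtaa\n"
            "//\n"
        )
        with caplog.at_level("WARNING"):
            (ref,) = read_references(gb)
        assert (ref.cds_start, ref.cds_end) == (0, 6)
        assert "no CDS" in caplog.text

    def test_genbank_joined_cds_rejected(self):
        gb = (
            "LOCUS       spliced               15 bp    DNA     linear   UNA 01-JAN-2000\n"
            "FEATURES             Location/Qualifiers\n"
            "     CDS             join(1..6,10..15)\n"
            "ORIGIN\n"
            "        1 atgaaatttg ggtaa\n"
            "//\n"
        )
        with pytest.raises(errors.ReferenceFormatError, match="spliced"):
            read_references(gb)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(errors.ReferenceFormatError, match="duplicate"):
            read_references(">a\nACGT\n>a\nTTTT\n")

    def test_empty_sequence_rejected(self):
        with pytest.raises(errors.ReferenceFormatError):
            read_references("id,sequence\nr1,\n")


class TestArchive:
    def make_zip(self, members: dict[str, bytes]) -> bytes:
        buf = io.BytesIO()
        with zipfile.ZipFile(buf, "w") as zf:
            for name, data in members.items():
                zf.writestr(name, data)
        return buf.getvalue()

    def test_archive_order_and_names(self, rng):
        chroms = [random_chromatogram(rng, n_bases=8) for _ in range(3)]
        blob = self.make_zip({f"t{i}.ab1": serialize(c) for i, c in enumerate(chroms)})
        parsed = read_trace_archive(blob)
        assert [p.source_name for p in parsed] == ["t0", "t1", "t2"]
        for p, c in zip(parsed, chroms):
            assert p.bases == c.bases

    def test_non_ab1_members_skipped_with_warning(self, rng, caplog):
        c = random_chromatogram(rng, n_bases=5)
        blob = self.make_zip({"readme.txt": b"hello", "x.ab1": serialize(c)})
        with caplog.at_level("WARNING"):
            parsed = read_trace_archive(blob)
        assert len(parsed) == 1
        assert "readme.txt" in caplog.text

    def test_empty_archive_is_empty_input(self):
        with pytest.raises(errors.EmptyInputError):
            read_trace_archive(self.make_zip({"notes.md": b"x"}))

    def test_corrupt_zip_is_archive_error(self):
        with pytest.raises(errors.ArchiveError):
            read_trace_archive(b"not a zip at all")
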