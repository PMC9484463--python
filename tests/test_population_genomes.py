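"""Sequence/variant I/O, singleton filtering, and sequence materialization."""

import pytest

from mircrosstalk.population_genomes import (
    EcotypePanel,
    PanelError,
    SequenceRecord,
    VariantRecord,
    filter_singletons,
    materialize,
    materialize_all,
    read_fasta,
    read_variants,
    variant_density,
    write_fasta,
)


def _vcf(tmp_path, body, ecotypes=("e1", "e2", "e3"), contigs=()):
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    for cid, length in contigs:
        lines.append(f"##contig=<ID={cid},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ecotypes)
    )
    lines += body
    path = tmp_path / "test.vcf"
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadFasta:
    def test_count_and_canonicalization(self, tmp_path):
        p = tmp_path / "m.fa"
        p.write_text(">m1\nacguacguacguacguacgua\n>m2\nACGTACGTACGTACGTACGTA\n")
        records = read_fasta(p, "mirna")
        assert len(records) == 2
        assert records["m1"].sequence == "ACGUACGUACGUACGUACGUA"
        assert records["m2"].sequence == "ACGUACGUACGUACGUACGUA"  # T -> U

    def test_transcripts_use_dna_alphabet(self, tmp_path):
        p = tmp_path / "t.fa"
        p.write_text(">t1\nacgu\n")
        assert read_fasta(p, "transcript")["t1"].sequence == "ACGT"

    def test_empty_file_gives_empty_collection(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        assert read_fasta(p, "transcript") == {}

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "dup.fa"
        p.write_text(">x\nACGT\n>x\nACGT\n")
        with pytest.raises(PanelError, match="duplicate"):
            read_fasta(p, "transcript")

    def test_malformed_header_names_line(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text("ACGT\n>x\nACGT\n")
        with pytest.raises(PanelError, match="line 1"):
            read_fasta(p, "transcript")

    def test_mirna_length_bounds(self):
        with pytest.raises(ValueError, match="length"):
            SequenceRecord("short", "mirna", "ACGU")

    def test_roundtrip(self, tmp_path):
        records = {
            "a": SequenceRecord("a", "transcript", "ACGTACGT"),
            "b": SequenceRecord("b", "transcript", "TTTTCCCC"),
        }
        path = tmp_path / "rt.fa"
        write_fasta(records.values(), path)
        back = read_fasta(path, "transcript")
        assert {k: v.sequence for k, v in back.items()} == {
            k: v.sequence for k, v in records.items()
        }


class TestReadVariants:
    SEQS = {"t1": SequenceRecord("t1", "transcript", "ACGTACGTAC")}

    def test_snp_with_three_carriers(self, tmp_path):
        path = _vcf(
            tmp_path,
            ["t1\t3\t.\tG\tA\t.\tPASS\t.\tGT\t1|1\t1|1\t0|1"],
            contigs=[("t1", 10)],
        )
        (v,) = read_variants(path, self.SEQS)
        assert v.carriers == {"e1", "e2", "e3"}  # het counts as carrier
        assert v.is_snp

    def test_indel_classified_by_length(self, tmp_path):
        path = _vcf(
            tmp_path,
            ["t1\t1\t.\tAC\tA\t.\tPASS\t.\tGT\t1|1\t0|0\t0|0"],
            contigs=[("t1", 10)],
        )
        (v,) = read_variants(path, self.SEQS)
        assert v.is_indel

    def test_multiallelic_split(self, tmp_path):
        path = _vcf(
            tmp_path,
            ["t1\t3\t.\tG\tA,C\t.\tPASS\t.\tGT\t1|1\t2|2\t0|0"],
            contigs=[("t1", 10)],
        )
        variants = read_variants(path, self.SEQS)
        assert len(variants) == 2
        assert variants[0].carriers == {"e1"} and variants[1].carriers == {"e2"}

    def test_ref_mismatch_rejected(self, tmp_path):
        path = _vcf(
            tmp_path,
            ["t1\t3\t.\tT\tA\t.\tPASS\t.\tGT\t1|1\t0|0\t0|0"],
            contigs=[("t1", 10)],
        )
        with pytest.raises(PanelError, match="disagrees"):
            read_variants(path, self.SEQS)

    def test_position_outside_sequence_rejected(self, tmp_path):
        path = _vcf(
            tmp_path,
            ["t1\t99\t.\tA\tC\t.\tPASS\t.\tGT\t1|1\t0|0\t0|0"],
            contigs=[("t1", 10)],
        )
        with pytest.raises(PanelError, match="outside"):
            read_variants(path, self.SEQS)


class TestFilterSingletons:
    def test_boundary(self):
        v1 = VariantRecord("t1", 1, "A", "C", frozenset(["e1"]))
        v2 = VariantRecord("t1", 2, "C", "G", frozenset(["e1", "e2"]))
        assert filter_singletons([v1, v2]) == [v2]

    def test_empty(self):
        assert filter_singletons([]) == []


class TestMaterialize:
    def _panel(self, variants):
        seqs = {
            "m1": SequenceRecord("m1", "mirna", "UUCGAUUCGAUUCGAUUCGA"),
            "t1": SequenceRecord("t1", "transcript", "ACGTACGTAC"),
        }
        return EcotypePanel(
            ecotypes=["e1", "e2", "e3"], sequences=seqs, variants=variants
        )

    def test_snp_substitution(self):
        panel = self._panel(
            [VariantRecord("m1", 3, "C", "A", frozenset(["e1"]))]
        )
        m = materialize(panel, "m1", "e1")
        assert m.status == "mutant"
        assert m.sequence == "UUAGAUUCGAUUCGAUUCGA"

    def test_indel_discards(self):
        panel = self._panel(
            [VariantRecord("t1", 2, "CG", "C", frozenset(["e1"]))]
        )
        m = materialize(panel, "t1", "e1")
        assert m.status == "discarded" and m.sequence is None

    def test_wild_identity(self):
        panel = self._panel([])
        m = materialize(panel, "t1", "e2")
        assert m.status == "wild"
        assert m.sequence == panel.sequences["t1"].sequence

    def test_conflicting_alleles_rejected(self):
        panel = self._panel(
            [
                VariantRecord("t1", 2, "C", "A", frozenset(["e1"])),
                VariantRecord("t1", 2, "C", "T", frozenset(["e1"])),
            ]
        )
        with pytest.raises(PanelError, match="conflict"):
            materialize(panel, "t1", "e1")

    def test_status_partition_covers_all_ecotypes(self):
        panel = self._panel(
            [
                VariantRecord("t1", 2, "CG", "C", frozenset(["e1"])),
                VariantRecord("t1", 4, "T", "A", frozenset(["e2"])),
            ]
        )
        statuses = [
            materialize(panel, "t1", eco).status for eco in panel.ecotypes
        ]
        assert sorted(statuses) == ["discarded", "mutant", "wild"]
        everything = materialize_all(panel)
        assert sum(len(v) for v in everything.values()) == len(panel.ecotypes) * len(
            panel.sequences
        )


class TestVariantDensity:
    def test_arithmetic(self):
        variants = [
            VariantRecord("t1", i + 1, "A", "C", frozenset(["e1", "e2"]))
            for i in range(10)
        ]
        assert variant_density(variants, None, 500) == 20.0
        assert variant_density([], None, 500) == 0.0

    def test_genome_scale_rate(self):
        variants = [
            VariantRecord("t1", 1, "A", "C", frozenset(["e1", "e2"]))
        ] * 64160
        assert variant_density(variants, None, 1_000_000) == pytest.approx(64.16)

    def test_zero_span_rejected(self):
        with pytest.raises(ValueError):
            variant_density([], None, 0)
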