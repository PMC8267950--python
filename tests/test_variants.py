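"""The eleven-criterion variant hard-filter cascade."""

import numpy as np
import pytest

from mifish import VariantRecord, apply_filters, filter_table
from mifish.simulate import simulate_variant_table
from mifish.variants import read_annotated_variants, write_annotated_variants


def record(**overrides):
    base = dict(
        sample_id="S1",
        gene="ESR1",
        chrom="chr6",
        pos=152_011_000,
        ref="A",
        alt="G",
        caller_pass=True,
        alt_fraction=0.35,
        total_depth=100,
        alt_depth=35,
        qual=90.0,
        mapq=60.0,
        dbnsfp_impact="high",
        is_common_snp=False,
        af_exac=0.0,
        af_esp_global=0.0,
        maf_ea=0.0,
        cosmic_case_count=150,
        n_samples_with_variant=1,
    )
    base.update(overrides)
    return VariantRecord(**base)


class TestApplyFilters:
    def test_clean_record_passes_all(self):
        verdict = apply_filters(record())
        assert verdict.passed and verdict.failed_criteria == ()

    @pytest.mark.parametrize(
        "overrides,criterion",
        [
            (dict(caller_pass=False), 1),
            (dict(alt_fraction=0.05, alt_depth=5), 2),  # boundary inclusive
            (dict(total_depth=5, alt_depth=5, alt_fraction=1.0), 3),
            (dict(alt_depth=3, alt_fraction=0.3), 3),
            (dict(qual=29.9), 4),
            (dict(dbnsfp_impact="low"), 5),
            (dict(is_common_snp=True), 6),
            (dict(af_exac=0.002), 7),
            (dict(af_esp_global=0.01), 7),
            (dict(maf_ea=0.5), 7),
            (dict(mapq=39.0), 8),  # COSMIC-recurrent branch
            (dict(mapq=50.0, cosmic_case_count=3, gene="ESR1"), 9),
            (dict(n_samples_with_variant=2, cosmic_case_count=50), 10),
            (dict(cosmic_case_count=0, dbnsfp_impact="moderate"), 11),
        ],
    )
    def test_each_criterion_fires(self, overrides, criterion):
        verdict = apply_filters(record(**overrides))
        assert criterion in verdict.failed_criteria

    def test_hotspot_gene_uses_lenient_mapq_tier(self):
        """TP53 at MAPQ 45 passes both MAPQ criteria; a non-hotspot,
        low-COSMIC gene at MAPQ 50 fails the 55 tier."""
        good = apply_filters(record(gene="TP53", mapq=45.0, cosmic_case_count=500))
        assert 8 not in good.failed_criteria and 9 not in good.failed_criteria
        bad = apply_filters(record(gene="ESR1", mapq=50.0, cosmic_case_count=3))
        assert bad.failed_criteria == (9,)

    def test_recurrent_low_cosmic_variant_shared_across_samples(self):
        shared = [
            record(sample_id=s, cosmic_case_count=0, pos=555)
            for s in ("S1", "S2", "S3")
        ]
        kept, audit = filter_table(shared)
        assert kept == []
        assert all("10" in row for row in audit["failed_criteria"])

    def test_failures_accumulate_not_short_circuit(self):
        verdict = apply_filters(
            record(caller_pass=False, qual=10.0, is_common_snp=True)
        )
        assert verdict.failed_criteria == (1, 4, 6)


class TestFilterTable:
    def test_engineered_fixture_exact_kept_count(self):
        records, expected = simulate_variant_table(60, 0.25, seed=3)
        kept, audit = filter_table(records)
        assert len(kept) == 15
        assert list(audit["passed"]) == [p for p, _ in expected]

    def test_order_independence(self):
        records, _ = simulate_variant_table(40, 0.5, seed=9)
        rng = np.random.default_rng(0)
        shuffled = list(records)
        rng.shuffle(shuffled)
        _, audit_a = filter_table(records)
        _, audit_b = filter_table(shuffled)
        key = ["sample_id", "chrom", "pos", "ref", "alt"]
        merged = audit_a.merge(audit_b, on=key, suffixes=("_a", "_b"))
        assert len(merged) == len(records)
        assert (merged["passed_a"] == merged["passed_b"]).all()
        assert (merged["failed_criteria_a"] == merged["failed_criteria_b"]).all()

    def test_tightening_cosmic_trust_never_keeps_more(self):
        records, _ = simulate_variant_table(80, 0.4, seed=11)
        kept_counts = [
            len(filter_table(records, cosmic_recurrent_min=m)[0])
            for m in (100, 200, 500)
        ]
        assert kept_counts == sorted(kept_counts, reverse=True)

    def test_empty_table(self):
        kept, audit = filter_table([])
        assert kept == [] and audit.empty


class TestFilterVcf:
    def test_vcf_round_trip_keeps_passing_variants(self, tmp_path):
        from mifish.variants import filter_vcf

        records, expected = simulate_variant_table(10, 0.5, seed=4)
        ann = tmp_path / "ann.tsv"
        write_annotated_variants(records, ann)
        vcf_in = tmp_path / "in.vcf"
        lines = ["##fileformat=VCFv4.2", "##contig=<ID=chr17>",
                 "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
        for r in records:
            lines.append(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t100\tPASS\t.")
        vcf_in.write_text("\n".join(lines) + "\n")
        n_in, n_kept = filter_vcf(
            vcf_in, ann, tmp_path / "out.vcf", tmp_path / "audit.tsv"
        )
        assert n_in == 10
        assert n_kept == sum(1 for p, _ in expected if p)
        out_text = (tmp_path / "out.vcf").read_text()
        kept_pos = {r.pos for r, (p, _) in zip(records, expected) if p}
        for pos in kept_pos:
            assert f"\t{pos}\t" in out_text


class TestSidecarIO:
    def test_round_trip(self, tmp_path):
        records, _ = simulate_variant_table(12, 0.5, seed=2)
        path = tmp_path / "ann.tsv"
        write_annotated_variants(records, path)
        loaded = read_annotated_variants(path)
        assert [r.key for r in loaded] == [r.key for r in records]
        assert [r.cosmic_case_count for r in loaded] == [
            r.cosmic_case_count for r in records
        ]

    def test_missing_column_is_an_error(self, tmp_path):
        records, _ = simulate_variant_table(3, 1.0, seed=1)
        path = tmp_path / "ann.tsv"
        write_annotated_variants(records, path)
        text = path.read_text().splitlines()
        header = text[0].split("\t")
        drop = header.index("mapq")
        trimmed = [
            "\t".join(c for i, c in enumerate(line.split("\t")) if i != drop)
            for line in text
        ]
        path.write_text("\n".join(trimmed) + "\n")
        with pytest.raises(ValueError, match="mapq"):
            read_annotated_variants(path)
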