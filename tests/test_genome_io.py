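"""Genome model and table I/O: validation, round-trips, normalization."""

import numpy as np
import pandas as pd
import pytest

from mafoot.genome import (
    DepthProfile,
    FormatError,
    GenomeDef,
    Interval,
    MarkerTable,
    ValidationError,
    VariantCall,
    normalize_depth,
    read_depth_windows,
    read_variants,
    write_variants,
)


def make_call(**kw):
    base = dict(
        line_id="L1", chrom="chr1", pos=100, ref="C", alt="T",
        var_type="substitution", qual=200.0, depth=80, alt_fwd=20,
        alt_rev=22, callers=frozenset({"A", "B"}),
    )
    base.update(kw)
    return VariantCall(**base)


class TestDataModel:
    def test_interval_merging_normalizes_repeat_mask(self):
        g = GenomeDef(
            chromosomes=(("chr1", 1000),),
            repeat_mask=(Interval("chr1", 50, 100), Interval("chr1", 80, 150)),
        )
        assert g.repeat_mask == (Interval("chr1", 50, 150),)

    @pytest.mark.parametrize(
        "kw",
        [
            dict(alt_fwd=50, alt_rev=40, depth=80),  # support > depth
            dict(ref=""),
            dict(ref="CA"),  # substitution must be 1 bp
            dict(pos=0),
            dict(var_type="snv"),
        ],
    )
    def test_variant_invariants_rejected(self, kw):
        with pytest.raises(ValidationError):
            make_call(**kw)

    def test_marker_table_requires_increasing_positions(self):
        df = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "pos": [200, 100],
            "allele_p1": ["A", "A"], "allele_p2": ["G", "G"],
            "depth_p1": [10, 10], "depth_p2": [10, 10],
        })
        with pytest.raises(ValidationError):
            MarkerTable(df)

    def test_depth_profile_rejects_overlapping_windows(self):
        df = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "start": [1, 50],
            "end": [100, 150], "raw_depth": [10.0, 10.0],
        })
        with pytest.raises(ValidationError):
            DepthProfile(df)


class TestVariantIO:
    def test_empty_table_round_trips(self, tmp_path):
        p = tmp_path / "empty.tsv"
        write_variants([], p)
        assert read_variants(p, "tsv") == []

    def test_round_trip_is_identity(self, tmp_path):
        calls = [
            make_call(pos=10),
            make_call(pos=20, ref="C", alt="CAT", var_type="insertion"),
            make_call(pos=30, in_ancestor=True, callers=frozenset({"A"})),
        ]
        p = tmp_path / "v.tsv"
        write_variants(calls, p)
        assert read_variants(p, "tsv") == calls
        # second round trip: stable representation
        write_variants(read_variants(p, "tsv"), tmp_path / "v2.tsv")
        assert (tmp_path / "v.tsv").read_text() == (tmp_path / "v2.tsv").read_text()

    def test_invalid_row_raises_not_dropped(self, tmp_path):
        p = tmp_path / "bad.tsv"
        write_variants([make_call()], p)
        text = p.read_text().replace("\t80\t20\t22\t", "\t10\t20\t22\t")
        p.write_text(text)
        with pytest.raises(ValidationError):
            read_variants(p, "tsv")

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "cols.tsv"
        p.write_text("line_id\tchrom\tpos\nL1\tchr1\t5\n")
        with pytest.raises(FormatError):
            read_variants(p, "tsv")

    def test_position_outside_genome_rejected(self, tmp_path, genome):
        p = tmp_path / "v.tsv"
        write_variants([make_call(pos=10**9)], p)
        with pytest.raises(ValidationError):
            read_variants(p, "tsv", genome=genome)

    def test_vcf_dialect(self, tmp_path):
        vcf = tmp_path / "calls.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">\n'
            '##INFO=<ID=SAF,Number=1,Type=Integer,Description="alt fwd">\n'
            '##INFO=<ID=SAR,Number=1,Type=Integer,Description="alt rev">\n'
            '##INFO=<ID=CALLERS,Number=1,Type=String,Description="callers">\n'
            "##contig=<ID=chr1,length=400000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t1234\t.\tC\tT\t187.5\t.\tDP=90;SAF=30;SAR=28;CALLERS=A,B\n"
            "chr1\t2000\t.\tG\tGTT\t99.0\t.\tDP=40;SAF=10;SAR=9;CALLERS=A,B\n"
        )
        calls = read_variants(vcf, "vcf", line_id="L7")
        assert [c.pos for c in calls] == [1234, 2000]
        assert calls[0].qual == 187.5
        assert calls[0].alt_fwd == 30 and calls[0].alt_rev == 28
        assert calls[0].callers == frozenset({"A", "B"})
        assert calls[1].var_type == "insertion"


class TestDepthIO:
    def test_bed_coordinates_shift_to_one_based(self, tmp_path):
        p = tmp_path / "d.bed"
        p.write_text("chr1\t0\t100\t55\nchr1\t100\t200\t60\n")
        df = read_depth_windows(p, format="bed")
        assert df["start"].tolist() == [1, 101]
        assert df["end"].tolist() == [100, 200]


class TestNormalizeDepth:
    def windows(self, genome, depth_nuclear, depth_mito=None):
        rows = []
        for chrom in genome.nuclear_chromosomes():
            L = genome.length_of(chrom)
            for s in range(1, L, 10_000):
                rows.append((chrom, s, min(s + 9_999, L), depth_nuclear))
        if depth_mito is not None:
            L = genome.length_of(genome.mito_name)
            for s in range(1, L, 100):
                rows.append((genome.mito_name, s, min(s + 99, L), depth_mito))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "raw_depth"])

    def test_constant_depth_normalizes_to_one(self, genome):
        prof = normalize_depth(self.windows(genome, 100.0), genome)
        assert np.allclose(prof.windows["norm_depth"], 1.0)

    def test_double_depth_window_maps_to_two(self, genome):
        df = self.windows(genome, 100.0)
        df.loc[30, "raw_depth"] = 200.0
        prof = normalize_depth(df, genome)
        assert prof.windows.loc[30, "norm_depth"] == pytest.approx(2.0)

    def test_mito_scaling(self, genome):
        prof = normalize_depth(self.windows(genome, 100.0, depth_mito=2000.0), genome)
        mito = prof.on(genome.mito_name)
        assert np.allclose(mito["norm_depth"], 20.0)

    @pytest.mark.parametrize("c", [0.5, 3.0, 117.0])
    def test_scale_invariance(self, genome, c):
        df = self.windows(genome, 100.0)
        rng = np.random.default_rng(5)
        df["raw_depth"] = rng.uniform(50, 150, size=len(df))
        base = normalize_depth(df, genome).windows["norm_depth"]
        scaled_df = df.assign(raw_depth=df["raw_depth"] * c)
        scaled = normalize_depth(scaled_df, genome).windows["norm_depth"]
        assert np.allclose(base, scaled)

    def test_all_zero_nuclear_depth_errors(self, genome):
        with pytest.raises(ValidationError):
            normalize_depth(self.windows(genome, 0.0), genome)
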