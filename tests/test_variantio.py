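"""Variant I/O: format round trips, filtering, effect annotation, catalogs."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from clonalclock import variantio
from clonalclock.signatures import CHANNELS_96, channel_of, synthetic_catalog

VCF_HEADER = """\
##fileformat=VCFv4.3
##contig=<ID=c1,length=100000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _write(tmp_path, body, name="t.vcf"):
    p = tmp_path / name
    p.write_text(VCF_HEADER + body)
    return p


def test_reads_toy_vcf_records(tmp_path):
    p = _write(tmp_path, "c1\t10\t.\tA\tG\t50\t.\tDP=100;AF=0.25\n"
                         "c1\t20\t.\tC\tT\t60\t.\tDP=80;AF=0.5\n"
                         "c1\t30\t.\tG\tA\t70\t.\tDP=90;AF=0.1\n")
    df = variantio.read_variants(p)
    assert len(df) == 3
    np.testing.assert_allclose(df["f"], [0.25, 0.5, 0.1])


def test_multiallelic_site_splits_into_two_records(tmp_path):
    p = _write(tmp_path, "c1\t10\t.\tA\tG,T\t50\t.\tDP=100;AF=0.2,0.3\n")
    df = variantio.read_variants(p)
    assert len(df) == 2
    assert sorted(df["alt"]) == ["G", "T"]
    np.testing.assert_allclose(sorted(df["f"]), [0.2, 0.3])


def test_empty_vcf_body_gives_empty_table(tmp_path):
    df = variantio.read_variants(_write(tmp_path, ""))
    assert len(df) == 0


def test_non_snv_rows_skipped(tmp_path):
    p = _write(tmp_path, "c1\t10\t.\tAT\tA\t50\t.\tDP=100;AF=0.2\n"
                         "c1\t20\t.\tC\tT\t60\t.\tDP=80;AF=0.5\n")
    df = variantio.read_variants(p)
    assert len(df) == 1 and df.loc[0, "pos"] == 20


def test_vcf_round_trip_preserves_fields(tmp_path, small_expansion):
    from clonalclock import sim
    table, _ = small_expansion
    noisy = sim.attach_sequencing_noise(table, 80, 2, seed=1)
    path = tmp_path / "out.vcf"
    variantio.write_variants(noisy, path)
    back = variantio.read_variants(path)
    assert len(back) == len(noisy)
    left = noisy.sort_values("pos").reset_index(drop=True)
    right = back.sort_values("pos").reset_index(drop=True)
    for col in ["pos", "depth", "alt_depth"]:
        np.testing.assert_array_equal(left[col].astype(int), right[col].astype(int))
    # TRUEF survives only at VCF float32 precision
    np.testing.assert_allclose(left["true_f"], right["true_f"], rtol=1e-5)
    assert (left["context"] == right["context"]).all()
    assert (left["effect"] == right["effect"]).all()


def test_tsv_round_trip(tmp_path, toy_variants):
    p = tmp_path / "v.tsv"
    variantio.write_variants(toy_variants, p)
    back = variantio.read_variants(p)
    pd.testing.assert_frame_equal(back[toy_variants.columns], toy_variants)


class TestFilters:
    def test_hand_enumerated_strict_filter(self, toy_variants):
        """qual>=35, 50<=depth<=200, alt>=3 keeps exactly the first record."""
        spec = variantio.FilterSpec(min_qual=35, min_depth=50, max_depth=200,
                                    min_alt_depth=3)
        out, report = variantio.apply_filters(toy_variants, spec)
        assert len(out) == 1 and out.loc[0, "pos"] == 100
        assert report["kept"] == 1 and report["input"] == 5

    def test_no_thresholds_is_identity(self, toy_variants):
        spec = variantio.FilterSpec(min_qual=None, min_depth=None,
                                    max_depth=None, min_alt_depth=None)
        out, _ = variantio.apply_filters(toy_variants, spec)
        pd.testing.assert_frame_equal(out, toy_variants)

    def test_filtering_is_idempotent(self, toy_variants):
        spec = variantio.FilterSpec()
        once, _ = variantio.apply_filters(toy_variants, spec)
        twice, _ = variantio.apply_filters(once, spec)
        pd.testing.assert_frame_equal(once, twice)

    def test_everything_below_quality_gives_empty(self, toy_variants):
        out, _ = variantio.apply_filters(toy_variants,
                                         variantio.FilterSpec(min_qual=1000))
        assert len(out) == 0

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            variantio.FilterSpec(min_depth=100, max_depth=50)


class TestAnnotateEffect:
    def _model(self, seq, start=101):
        return variantio.CodingModel([variantio.CodingSequence("c1", start, seq)])

    def test_silent_third_position(self):
        model = self._model("TTTAAA")
        assert variantio.annotate_effect("c1", 103, "T", "C", model) == "syn"

    def test_stopgain(self):
        model = self._model("TATAAA")
        assert variantio.annotate_effect("c1", 103, "T", "A", model) == "stopgain"

    def test_outside_cds_is_noncoding(self):
        model = self._model("TTTAAA")
        assert variantio.annotate_effect("c1", 5, "A", "G", model) == "noncoding"

    def test_cds_length_must_be_codon_multiple(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            variantio.CodingSequence("c1", 1, "TTTA")

    def test_agrees_with_translation_oracle_on_all_codons(self):
        """All 64 codons x 9 single-base changes against Biopython translation."""
        bases = "ACGT"
        for codon in ("".join([a, b, c]) for a in bases for b in bases for c in bases):
            model = self._model(codon, start=1)
            aa_old = str(Seq(codon).translate())
            if aa_old == "*":
                continue  # mutations out of stops are outside the annotator's scope
            for i in range(3):
                for alt in bases.replace(codon[i], ""):
                    got = variantio.annotate_effect("c1", i + 1, codon[i], alt, model)
                    new = codon[:i] + alt + codon[i + 1:]
                    aa_new = str(Seq(new).translate())
                    want = ("syn" if aa_new == aa_old
                            else "stopgain" if aa_new == "*" else "nonsyn")
                    assert got == want, (codon, i, alt)


class TestSignatureCatalog:
    def test_valid_catalog_reads_and_column_sums_are_one(self, tmp_path):
        p = tmp_path / "cat.tsv"
        synthetic_catalog().to_csv(p, sep="\t")
        cat = variantio.read_signature_catalog(p)
        assert cat.shape == (96, 3)
        np.testing.assert_allclose(cat.sum(axis=0), 1.0, atol=1e-6)

    def test_shuffled_rows_reordered_by_label(self, tmp_path):
        cat = synthetic_catalog()
        p = tmp_path / "shuf.tsv"
        cat.sample(frac=1.0, random_state=0).to_csv(p, sep="\t")
        back = variantio.read_signature_catalog(p)
        assert list(back.index) == list(CHANNELS_96)
        np.testing.assert_allclose(back.to_numpy(), cat.to_numpy())

    def test_tolerant_renormalisation_and_rejection(self, tmp_path):
        cat = synthetic_catalog().copy()
        cat["SBS1"] *= 0.999
        p = tmp_path / "near.tsv"
        cat.to_csv(p, sep="\t")
        back = variantio.read_signature_catalog(p)
        np.testing.assert_allclose(back["SBS1"].sum(), 1.0, atol=1e-9)
        cat["SBS1"] *= 0.5
        cat.to_csv(p, sep="\t")
        with pytest.raises(ValueError, match="sum to 1"):
            variantio.read_signature_catalog(p)

    def test_negative_entries_rejected(self, tmp_path):
        cat = synthetic_catalog().copy()
        cat.iloc[0, 0] = -0.01
        p = tmp_path / "neg.tsv"
        cat.to_csv(p, sep="\t")
        with pytest.raises(ValueError, match="negative"):
            variantio.read_signature_catalog(p)

    def test_wrong_row_count_rejected(self, tmp_path):
        cat = synthetic_catalog().iloc[:95]
        p = tmp_path / "short.tsv"
        cat.to_csv(p, sep="\t")
        with pytest.raises(ValueError, match="96"):
            variantio.read_signature_catalog(p)


def test_purine_contexts_collapse_to_pyrimidine_channels():
    # G>A centred in TGC maps, by reverse complement, to C>T centred in GCA
    assert channel_of("G", "A", "TGC") == "G[C>T]A"
    assert channel_of("C", "T", "GCA") == "G[C>T]A"
    with pytest.raises(ValueError):
        channel_of("C", "T", "GAA")
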