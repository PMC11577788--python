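"""Barcode template parsing, space enumeration, extraction and diversity."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodeq import (
    classify_barcode,
    diversity_stats,
    enumerate_space,
    expected_unique_barcodes,
    extract_barcode,
    instantiate_oligo,
    parse_template,
    simulate_unique_barcodes,
)
from barcodeq import reference as ref
from barcodeq._seq import revcomp
from barcodeq.barcode_model import TemplateFormatError

BARCODES = st.text(alphabet="ACGT", min_size=6, max_size=6)


class TestParseTemplate:
    def test_published_template_offsets_and_flanks(self, template):
        assert template.degenerate_offsets == (30, 36, 37, 38, 39, 42)
        assert len(template.sequence) == 80
        assert template.flank_left == template.sequence[18:30]
        assert template.flank_right == template.sequence[43:55]
        assert template.role_map == {
            1: "wobble", 2: "codon1", 3: "codon2", 4: "codon3", 5: "wobble", 6: "wobble",
        }

    def test_no_degenerate_positions_rejected(self):
        with pytest.raises(TemplateFormatError):
            parse_template(ref.BARCODE_TEMPLATE_OLIGO.replace("N", "A"))

    def test_wrong_arrangement_rejected(self):
        # move the lone 5' N next to the codon block
        seq = list(ref.BARCODE_TEMPLATE_OLIGO.upper())
        seq[30], seq[31] = seq[31], "N"
        seq[30] = "A"
        with pytest.raises(TemplateFormatError):
            parse_template("".join(seq))

    def test_non_iupac_character_rejected(self):
        with pytest.raises(ValueError, match="character"):
            parse_template(ref.BARCODE_TEMPLATE_OLIGO[:-1] + "X")


class TestClassifyBarcode:
    @pytest.mark.parametrize(
        "barcode,codon,aa",
        [
            ("TGACGT", "GTC", "V"),  # barcode of the cmbA-mutant oligo
            ("GTATCT", "ATA", "I"),  # barcode of the srtA-mutant oligo
        ],
    )
    def test_published_barcodes_functional(self, barcode, codon, aa):
        bc = classify_barcode(barcode)
        assert bc.replacement_codon == codon
        assert bc.replacement_aa == aa
        assert bc.functional

    def test_stop_replacement_is_nonfunctional(self):
        # positions 2-4 = TCA reverse-complement to the TGA stop
        bc = classify_barcode("ATCAAA")
        assert bc.replacement_aa == "*"
        assert not bc.functional

    @pytest.mark.parametrize("bad", ["ACGTA", "ACGTACG", "ACGTAX"])
    def test_bad_input_rejected(self, bad):
        with pytest.raises(ValueError):
            classify_barcode(bad)

    @given(bases=BARCODES)
    @settings(derandomize=True, max_examples=50)
    def test_functional_iff_sense(self, bases):
        bc = classify_barcode(bases)
        assert bc.functional == (bc.replacement_aa != "*")


class TestEnumerateSpace:
    def test_functional_space_size(self, template):
        space = enumerate_space(template)
        assert space.all_barcodes == 4096
        assert space.functional_count == 3904  # 4^3 wobbles x 61 sense codons
        assert space.nonfunctional_count == 192  # 4^3 x 3 stop codons

    def test_agrees_with_independent_brute_force(self, template, table):
        # oracle: classify all 4096 strings with Biopython translation only
        from Bio.Seq import Seq

        functional = set()
        for combo in itertools.product("ACGT", repeat=6):
            b = "".join(combo)
            codon = str(Seq(b[1:4]).reverse_complement())
            if str(Seq(codon).translate()) != "*":
                functional.add(b)
        space = enumerate_space(template, table)
        assert set(space.functional) == functional

    def test_codon_whitelist_restricts_space(self, template, table):
        # 24 sense codons admitted -> 4^3 x 24 barcodes
        sense = sorted(table.sense_codons)[:24]
        space = enumerate_space(template, codon_whitelist=sense)
        assert space.functional_count == 1536
        assert space.functional_count + space.nonfunctional_count == 4096

    def test_stop_codon_in_whitelist_rejected(self, template):
        with pytest.raises(ValueError, match="stop"):
            enumerate_space(template, codon_whitelist=["TAA"])


class TestInstantiateAndExtract:
    def test_reproduces_all_published_barcoded_oligos(self, template):
        for oligo_id, published in ref.BARCODED_OLIGOS.items():
            barcode = extract_barcode(published, template)
            assert barcode is not None, oligo_id
            assert instantiate_oligo(template, barcode).upper() == published.upper()

    def test_published_oligos_distinct_and_functional(self, template):
        barcodes = [extract_barcode(s, template) for s in ref.BARCODED_OLIGOS.values()]
        assert len(set(barcodes)) == 9
        assert all(classify_barcode(b).functional for b in barcodes)

    def test_extract_from_both_strands(self, template):
        oligo = ref.BARCODED_OLIGOS["oVPL3996"]
        assert extract_barcode(oligo, template) == "TGACGT"
        assert extract_barcode(revcomp(oligo), template) == "TGACGT"

    def test_random_sequence_unassigned(self, template):
        rng = np.random.default_rng(0)
        read = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        assert extract_barcode(read, template) is None

    def test_truncated_flank_unassigned(self, template):
        oligo = ref.BARCODED_OLIGOS["oVPL3996"]
        assert extract_barcode(oligo[25:], template) is None  # left flank cut

    @given(bases=BARCODES)
    @settings(derandomize=True, max_examples=50)
    def test_instantiate_extract_round_trip(self, bases, template):
        assert extract_barcode(instantiate_oligo(template, bases), template) == bases

    def test_length_mismatch_rejected(self, template):
        with pytest.raises(ValueError):
            instantiate_oligo(template, "ACGT")


class TestExpectedUnique:
    def test_single_draw(self):
        assert expected_unique_barcodes(1, 3904) == pytest.approx(1.0)

    def test_library_scale_value(self):
        # closed form for 96 draws from 3,904 equally likely barcodes
        assert expected_unique_barcodes(96, 3904) == pytest.approx(94.8413, abs=1e-3)

    def test_monotone_and_bounded(self):
        vals = [expected_unique_barcodes(k, 500) for k in range(0, 2000, 25)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert all(v <= 500 for v in vals)
        assert expected_unique_barcodes(10**6, 500) == pytest.approx(500, rel=1e-9)

    def test_nonpositive_library_rejected(self):
        with pytest.raises(ValueError):
            expected_unique_barcodes(10, 0)


class TestSimulateUnique:
    def test_mean_matches_closed_form(self):
        res = simulate_unique_barcodes(96, 3904, trials=4000, seed=11)
        se = res["sd"] / math.sqrt(4000)
        assert abs(res["mean"] - 94.8413) < 3 * se + 1e-9

    def test_degenerate_library(self):
        res = simulate_unique_barcodes(96, 1, trials=50, seed=0)
        assert res["mean"] == 1.0 and res["sd"] == 0.0

    def test_seed_reproducibility(self):
        a = simulate_unique_barcodes(30, 100, trials=200, seed=5)
        b = simulate_unique_barcodes(30, 100, trials=200, seed=5)
        assert a == b

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            simulate_unique_barcodes(
                10, 3904, trials=5, seed=0, position_weights=np.ones((6, 4))
            )


class TestDiversityStats:
    def test_single_repeated_barcode(self):
        stats = diversity_stats(["AAAAAA"] * 10)
        assert stats.observed_unique == 1
        assert np.allclose(stats.information_content, 2.0)
        assert stats.position_frequency.loc[1, "A"] == 10

    def test_uniform_position_has_zero_information(self):
        stats = diversity_stats(["AAAAAA", "CAAAAA", "GAAAAA", "TAAAAA"])
        assert stats.information_content[0] == pytest.approx(0.0)
        assert np.allclose(stats.information_content[1:], 2.0)

    def test_published_oligo_barcodes_spectrum(self, template):
        barcodes = [extract_barcode(s, template) for s in ref.BARCODED_OLIGOS.values()]
        stats = diversity_stats(barcodes)
        assert stats.observed_unique == 9
        assert len(stats.aa_spectrum) <= 8
        assert "*" not in stats.aa_spectrum
        assert stats.position_frequency.to_numpy().sum(axis=1).tolist() == [9] * 6

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            diversity_stats([])
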