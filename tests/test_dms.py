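"""Deep mutational scanning: variant calling, linking, scoring."""

import collections
import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from edrec.design import design_dms_library
from edrec.dms import (
    AmbiguousVariantError,
    LAMBDA_N_ORF_SYNTHETIC,
    LAMBDA_N_PEPTIDE,
    call_variant,
    link_barcodes,
    residue_summary,
    score_variants,
    scores_frame,
)
from edrec.readproc import DEFAULT_A_OFFSETS, EditTally
from edrec.simulate import EditingModel, simulate_linking_reads, simulate_tallies


class TestCallVariant:
    def test_reference_returns_wildtype(self):
        call = call_variant(LAMBDA_N_ORF_SYNTHETIC, LAMBDA_N_ORF_SYNTHETIC)
        assert call.is_wildtype

    def test_stop_codon_at_position_7(self):
        ref = "ATGGAT" + "CGT" * 6  # CGT at codons 3..8
        var = ref[:18] + "TAA" + ref[21:]
        call = call_variant(var, ref)
        assert (call.codon_position, call.codon, call.amino_acid) == (7, "TAA", "*")

    def test_all_64_codons_recover_the_genetic_code(self):
        """Codon-table oracle: 61 sense + 3 stop codons at one position."""
        ref = LAMBDA_N_ORF_SYNTHETIC
        aas = []
        for codon in map("".join, itertools.product("ACGT", repeat=3)):
            var = ref[:9] + codon + ref[12:]
            call = call_variant(var, ref)
            aas.append(
                str(Seq(codon).translate()) if call.is_wildtype else call.amino_acid
            )
        counts = collections.Counter(aas)
        assert counts["*"] == 3
        assert sum(counts.values()) == 64
        expected = collections.Counter(
            str(Seq("".join(c)).translate())
            for c in itertools.product("ACGT", repeat=3)
        )
        assert counts == expected

    def test_two_codon_difference_is_ambiguous(self):
        ref = LAMBDA_N_ORF_SYNTHETIC
        var = "TTT" + ref[3:9] + "TTT" + ref[12:]
        with pytest.raises(AmbiguousVariantError):
            call_variant(var, ref)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            call_variant("ATG", "ATGATG")


class TestLinkBarcodes:
    def test_clean_reads_recover_design_truth_exactly(self):
        _, bc_map = design_dms_library("ATGCGTGAA", barcodes_per_variant=2, seed=3)
        reads = simulate_linking_reads(bc_map, reads_per_barcode=3, seed=1)
        resolved, counters = link_barcodes(reads, "ATGCGTGAA", min_support=2)
        assert counters["undecodable"] == 0
        assert len(resolved) == len(bc_map)
        merged = resolved.merge(bc_map, on="barcode", suffixes=("_got", "_true"))
        non_wt = merged[~merged["is_wildtype"]]
        assert (
            non_wt["codon_position_got"] == non_wt["codon_position_true"]
        ).all()
        assert (non_wt["codon_got"] == non_wt["codon_true"]).all()
        # wild-type calls correspond to the reference codon at some position
        wt = merged[merged["is_wildtype"]]
        assert (wt["orf_sequence"] == "ATGCGTGAA").all()

    def test_impure_barcode_dropped(self):
        ref = "ATGCGT"
        reads = [("GGCCGGCCGG", ref)] * 5 + [("GGCCGGCCGG", "ATGTAA")] * 5
        resolved, counters = link_barcodes(reads, ref, min_support=2, min_purity=0.8)
        assert len(resolved) == 0 and counters["barcodes_dropped"] == 1

    def test_low_error_linking_resolves_most_barcodes(self):
        """1% per-base errors: >=99% of barcodes resolve to the truth."""
        _, bc_map = design_dms_library(
            LAMBDA_N_ORF_SYNTHETIC[:18], barcodes_per_variant=1, seed=4
        )
        reads = simulate_linking_reads(
            bc_map, reads_per_barcode=6, seed=2, error_rate=0.01
        )
        resolved, _ = link_barcodes(reads, LAMBDA_N_ORF_SYNTHETIC[:18], min_support=2)
        merged = resolved.merge(bc_map, on="barcode", suffixes=("_got", "_true"))
        non_wt = merged[~merged["is_wildtype"]]
        correct = (non_wt["codon_got"] == non_wt["codon_true"]) & (
            non_wt["codon_position_got"] == non_wt["codon_position_true"]
        )
        # nearly all barcodes resolve, and the resolved map is >=99% true
        assert len(merged) >= 0.95 * len(bc_map)
        assert correct.mean() >= 0.99


def _uniform_tallies(bc_map, frac_edited=0.3, n=200):
    """Tallies in which every barcode edits identically."""
    tallies = {}
    ge1 = int(round(frac_edited * n))
    for barcode in bc_map["barcode"]:
        hist = np.zeros(9, dtype=np.int64)
        hist[0], hist[1] = n - ge1, ge1
        counts = np.zeros((8, 4), dtype=np.int64)
        counts[:, 0] = n
        counts[0, 0], counts[0, 2] = n - ge1, ge1
        tallies[barcode] = EditTally(
            variant_key=barcode,
            refa_offsets=DEFAULT_A_OFFSETS,
            umi_count=n,
            base_counts=counts,
            edit_histogram=hist,
        )
    return tallies


class TestScoreVariants:
    def test_uniform_editing_gives_zero_log2_ratios(self):
        _, bc_map = design_dms_library("ATGCGTGAA", barcodes_per_variant=3, seed=5)
        tallies = _uniform_tallies(bc_map)
        scores, _ = score_variants(
            tallies, bc_map, wt_peptide="MRE", reference_orf="ATGCGTGAA",
            iters=100, seed=0,
        )
        assert scores
        for s in scores:
            assert s.log2_ratio_vs_wt == pytest.approx(0.0)

    def test_wildtype_normalization_idempotent(self):
        """Scoring a synonymous group identical to the WT pool gives exactly 0."""
        bc_map = pd.DataFrame(
            {
                "barcode": ["GGCC", "CCGG", "GCGC"],
                "codon_position": [2, 2, 2],
                "codon": ["CGC", "CGC", "CGC"],  # synonymous with CGT (Arg)
                "amino_acid": ["R", "R", "R"],
            }
        )
        tallies = _uniform_tallies(bc_map, frac_edited=0.4)
        scores, counters = score_variants(
            tallies, bc_map, wt_peptide="MR", iters=50, seed=1
        )
        assert counters["wt_barcodes"] == 3
        (score,) = scores
        assert score.log2_ratio_vs_wt == 0.0

    def test_two_level_simulation_recovers_log2_ratio_one(self):
        """Variants at rate 2r score one doubling above variants at r."""
        _, bc_map = design_dms_library(
            LAMBDA_N_ORF_SYNTHETIC[:12], barcodes_per_variant=4, seed=6
        )
        rng = np.random.default_rng(3)
        pep = str(Seq(LAMBDA_N_ORF_SYNTHETIC[:12]).translate())
        level = {}
        for row in bc_map.itertuples():
            key = (row.codon_position, row.amino_acid)
            if key not in level:
                synonymous = row.amino_acid == pep[row.codon_position - 1]
                level[key] = 1.0 if synonymous else rng.choice([1.0, 2.0])
        n = 4000
        tallies = {}
        for row in bc_map.itertuples():
            r = 0.1 * level[(row.codon_position, row.amino_acid)]
            ge1 = rng.binomial(n, r)
            hist = np.zeros(9, dtype=np.int64)
            hist[0], hist[1] = n - ge1, ge1
            counts = np.zeros((8, 4), dtype=np.int64)
            counts[:, 0] = n
            counts[0, 0], counts[0, 2] = n - ge1, ge1
            tallies[row.barcode] = EditTally(
                row.barcode, DEFAULT_A_OFFSETS, n, counts, hist
            )
        scores, _ = score_variants(
            tallies, bc_map, wt_peptide=pep,
            reference_orf=LAMBDA_N_ORF_SYNTHETIC[:12], iters=200, seed=0,
        )
        for s in scores:
            expected = np.log2(level[(s.codon_position, s.amino_acid)])
            assert s.log2_ratio_vs_wt == pytest.approx(expected, abs=0.25)

    def test_missing_wildtype_rejected(self):
        bc_map = pd.DataFrame(
            {
                "barcode": ["GGCC"],
                "codon_position": [1],
                "codon": ["TAA"],
                "amino_acid": ["*"],
            }
        )
        tallies = _uniform_tallies(bc_map)
        with pytest.raises(ValueError, match="wild-type"):
            score_variants(tallies, bc_map, wt_peptide="M", iters=10, seed=0)

    def test_scores_invariant_under_barcode_relabeling(self):
        _, bc_map = design_dms_library("ATGCGTGAA", barcodes_per_variant=3, seed=7)
        model = EditingModel()
        records, _ = design_dms_library("ATGCGTGAA", barcodes_per_variant=3, seed=7)
        tallies = simulate_tallies(records, model, 300, seed=8)
        relabel = {b: f"X{i:05d}" for i, b in enumerate(sorted(tallies))}
        tallies2 = {}
        for b, t in tallies.items():
            t2 = EditTally(
                relabel[b], t.refa_offsets, t.umi_count,
                t.base_counts.copy(), t.edit_histogram.copy(),
            )
            tallies2[relabel[b]] = t2
        bc_map2 = bc_map.assign(barcode=bc_map["barcode"].map(relabel))
        kwargs = dict(
            wt_peptide="MRE", reference_orf="ATGCGTGAA", iters=100, seed=0
        )
        scores1, _ = score_variants(tallies, bc_map, **kwargs)
        scores2, _ = score_variants(tallies2, bc_map2, **kwargs)
        f1, f2 = scores_frame(scores1), scores_frame(scores2)
        pd.testing.assert_frame_equal(
            f1.sort_values(["codon_position", "amino_acid"]).reset_index(drop=True),
            f2.sort_values(["codon_position", "amino_acid"]).reset_index(drop=True),
        )


class TestResidueSummary:
    def _scores(self, values):
        from edrec.dms import DmsScore

        out = []
        for (pos, aa), v in values.items():
            out.append(DmsScore(pos, aa, 4, 0.2, 0.1, 0.3, v, False))
        return out

    def test_all_zero_scores_give_zero_means(self):
        values = {(p, aa): 0.0 for p in (1, 2) for aa in "ACDE"}
        table = residue_summary(self._scores(values), wt_peptide="MR")
        assert (table["mean_log2_ratio"] == 0.0).all()

    def test_penalized_position_is_minimum(self):
        values = {(p, aa): 0.0 for p in (1, 2, 3) for aa in "ACDE"}
        for aa in "ACDE":
            values[(2, aa)] = -2.0
        table = residue_summary(self._scores(values), wt_peptide="MRM")
        worst = table.loc[table["mean_log2_ratio"].idxmin(), "codon_position"]
        assert worst == 2

    def test_means_match_groupby_oracle(self):
        rng = np.random.default_rng(4)
        values = {
            (p, aa): float(rng.normal())
            for p in range(1, 6)
            for aa in "ACDEFGH"
        }
        pep = "MMMMM"
        table = residue_summary(self._scores(values), wt_peptide=pep)
        frame = pd.DataFrame(
            [
                {"pos": p, "aa": aa, "v": v}
                for (p, aa), v in values.items()
                if aa != pep[p - 1] and aa != "*"
            ]
        )
        expected = frame.groupby("pos")["v"].mean()
        for row in table.itertuples():
            assert row.mean_log2_ratio == pytest.approx(expected[row.codon_position])

    def test_stops_excluded_by_default(self):
        values = {(1, "A"): -0.5, (1, "*"): -5.0}
        table = residue_summary(self._scores(values), wt_peptide="M")
        assert table.loc[0, "mean_log2_ratio"] == pytest.approx(-0.5)
        with_stops = residue_summary(
            self._scores(values), wt_peptide="M", include_stops=True
        )
        assert with_stops.loc[0, "mean_log2_ratio"] == pytest.approx(-2.75)
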