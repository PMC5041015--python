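"""Alignment, PFM/information content, consensus patterns and the
two-sample logo statistic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from parasign.classify import match_motif
from parasign.motif import (
    AlignedBlock,
    align_subgroup,
    build_pfm,
    column_information,
    derive_consensus_motif,
    select_motif_window,
    two_sample_logo,
    write_meme,
)

from _helpers import welch_oracle

AA = "ACDEFGHIKLMNPQRSTVWY"
RNG = np.random.default_rng(99)


def _block(rows, label="SG", ids=None):
    ids = ids or tuple(f"s{i}" for i in range(len(rows)))
    return AlignedBlock(label=label, ids=tuple(ids), rows=tuple(rows))


def _random_rows(n, width, rng=RNG):
    return ["".join(AA[i] for i in rng.integers(0, 20, width)) for _ in range(n)]


class TestAlignSubgroup:
    def test_identical_sequences_align_gap_free(self):
        seqs = {"a": "MKVHGHWLL", "b": "MKVHGHWLL", "c": "MKVHGHWLL"}
        block = align_subgroup(seqs)
        assert block.rows == ("MKVHGHWLL",) * 3
        assert block.ids == ("a", "b", "c")

    def test_single_substitution_gives_single_mismatch_column(self):
        block = align_subgroup({"a": "MKVHGHWLL", "b": "MKVHGHWIL"})
        assert block.n_columns == 9
        mismatches = [
            j for j in range(block.n_columns)
            if len(set(block.column(j))) > 1
        ]
        assert mismatches == [7]

    @pytest.mark.parametrize("method", ["center_star", "mafft"])
    def test_planted_motif_residues_share_columns(self, method, noiseless_scenario):
        sp = noiseless_scenario
        label = "sub1"
        members = [
            g for g, r in sp.truth.subgroup_of.items() if r.subgroup == label
        ][:8]
        proteins = {}
        for genome in sp.genomes:
            for gene in genome.genes():
                if gene.gene_id in members:
                    proteins[gene.gene_id] = gene.protein
        block = align_subgroup(proteins, method=method)
        record = sp.truth.subgroup_of[members[0]]
        # every literal of the planted pattern must occupy one conserved column
        offsets = [
            record.motif_start + p
            for p, c in enumerate(record.pattern)
            if c != "x"
        ]
        # map sequence offset -> column via the first row's residue coordinates
        for row_idx, gene_id in enumerate(block.ids):
            seq_pos = -1
            col_of = {}
            for j, c in enumerate(block.rows[row_idx]):
                if c != "-":
                    seq_pos += 1
                    col_of[seq_pos] = j
            for off, lit in zip(offsets, [c for c in record.pattern if c != "x"]):
                col = col_of[off]
                assert block.rows[row_idx][col] == lit
                if row_idx == 0:
                    assert set(block.column(col)) == {lit}

    def test_fewer_than_two_sequences_is_an_error(self):
        with pytest.raises(ValueError):
            align_subgroup({"a": "MKV"})

    def test_unknown_method_is_an_error(self):
        with pytest.raises(ValueError):
            align_subgroup({"a": "MKV", "b": "MKV"}, method="muscle")


class TestSelectMotifWindow:
    def test_conserved_run_in_random_background_is_found(self):
        rng = np.random.default_rng(5)
        width = 7
        n, total = 12, 40
        rows = _random_rows(n, total, rng)
        start = 17
        motif = "CHGHWEK"
        rows = [r[:start] + motif + r[start + width:] for r in rows]
        block = _block(rows)
        window = select_motif_window(block, width=width)
        assert window == (start, start + width)
        # exhaustive scan oracle
        info = column_information(block)
        sums = [info[s: s + width].sum() for s in range(total - width + 1)]
        assert window[0] == int(np.argmax(sums))

    def test_ties_break_leftmost(self):
        block = _block(["AAAAAAAA"] * 4)
        assert select_motif_window(block, width=3) == (0, 3)

    def test_full_width_window_is_the_whole_block(self):
        block = _block(_random_rows(4, 10))
        assert select_motif_window(block, width=10) == (0, 10)

    def test_width_larger_than_block_is_an_error(self):
        block = _block(_random_rows(3, 5))
        with pytest.raises(ValueError):
            select_motif_window(block, width=6)


class TestBuildPfm:
    def test_fully_conserved_column_has_maximal_information(self):
        block = _block(["H"] * 10)
        pfm = build_pfm(block)
        assert pfm.frequencies.loc["H", 0] == 1.0
        assert pfm.information[0] == pytest.approx(math.log2(20))

    def test_two_residue_column_loses_one_bit(self):
        block = _block(["C"] * 5 + ["E"] * 5)
        pfm = build_pfm(block)
        assert pfm.information[0] == pytest.approx(math.log2(20) - 1.0)

    def test_uniform_column_has_zero_information(self):
        block = _block([a for a in AA])  # one row per residue
        pfm = build_pfm(block)
        assert pfm.information[0] == pytest.approx(0.0)

    def test_all_gap_column_flagged_with_zero_information(self):
        block = _block(["A-C", "A-C", "A-C"])
        pfm = build_pfm(block)
        assert pfm.all_gap_columns == (1,)
        assert pfm.information[1] == 0.0

    def test_small_sample_correction_reduces_information(self):
        block = _block(_random_rows(6, 8))
        raw = build_pfm(block).information
        corrected = build_pfm(block, small_sample_correction=True).information
        assert (corrected <= raw + 1e-12).all()

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_frequencies_sum_to_one_and_information_is_bounded(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        width = int(rng.integers(1, 12))
        block = _block(_random_rows(n, width, rng))
        pfm = build_pfm(block)
        sums = pfm.frequencies.sum(axis=0)
        assert np.allclose(sums, 1.0)
        assert ((pfm.information >= 0) & (pfm.information <= math.log2(20) + 1e-9)).all()


class TestConsensusMotif:
    def _ptps_like_block(self, pattern, n=10, flank=4, rng=None):
        """Rows carrying the literal pattern with variable wildcard and
        flanking positions."""
        rng = rng or np.random.default_rng(3)
        rows = []
        for _ in range(n):
            left = "".join(AA[i] for i in rng.integers(0, 20, flank))
            right = "".join(AA[i] for i in rng.integers(0, 20, flank))
            core = "".join(
                c if c != "x" else AA[int(rng.integers(0, 20))] for c in pattern
            )
            rows.append(left + core + right)
        return _block(rows)

    @pytest.mark.parametrize("pattern", ["CxxxHGH", "CxxxxxHGH", "ExxHGH"])
    def test_planted_subfamily_patterns_are_recovered(self, pattern):
        block = self._ptps_like_block(pattern)
        window = select_motif_window(block, width=len(pattern) + 4)
        pfm = build_pfm(block, window=window)
        sig = derive_consensus_motif(pfm, conservation_threshold=0.9)
        assert sig.pattern == pattern

    def test_fully_conserved_block_gives_full_literal_pattern(self):
        block = _block(["CHGHWEK"] * 5)
        pfm = build_pfm(block)
        sig = derive_consensus_motif(pfm, conservation_threshold=0.9)
        assert sig.pattern == "CHGHWEK"

    def test_literal_positions_recount_above_threshold(self):
        block = self._ptps_like_block("CxxxHGH", n=12)
        pfm = build_pfm(block, window=select_motif_window(block, width=11))
        sig = derive_consensus_motif(pfm, conservation_threshold=0.9)
        freqs = pfm.frequencies
        for p, c in enumerate(sig.pattern):
            if c == "x":
                continue
            col = sig.window[0] - pfm.window[0] + p
            assert freqs.loc[c, col] >= 0.9 - 1e-12

    def test_members_match_their_own_signature_at_threshold_one(self):
        block = self._ptps_like_block("ExxHGH", n=8)
        pfm = build_pfm(block)
        sig = derive_consensus_motif(pfm, conservation_threshold=1.0)
        for row in block.rows:
            assert match_motif(row.replace("-", ""), sig) != []

    def test_all_wildcard_pattern_is_an_error(self):
        block = _block(_random_rows(12, 6, np.random.default_rng(8)))
        pfm = build_pfm(block)
        with pytest.raises(ValueError, match="no signature"):
            derive_consensus_motif(pfm, conservation_threshold=0.95)

    @pytest.mark.parametrize("threshold", [0.4, 1.2])
    def test_threshold_outside_half_one_is_an_error(self, threshold):
        block = _block(["CHG"] * 4)
        with pytest.raises(ValueError):
            derive_consensus_motif(build_pfm(block), threshold)


class TestTwoSampleLogo:
    def test_identical_groups_have_no_significant_cells(self):
        rows = _random_rows(6, 5, np.random.default_rng(1))
        res = two_sample_logo(_block(rows, "A"), _block(rows, "B"))
        assert res.significant_cells().empty

    def test_opposed_conserved_columns_flag_both_residues(self):
        a = _block(["C"] * 10, "A")
        b = _block(["E"] * 10, "B")
        res = two_sample_logo(a, b, alpha=0.05)
        sig = res.significant_cells().set_index("residue")
        assert sig.loc["C", "direction"] == "enriched"
        assert sig.loc["E", "direction"] == "depleted"
        assert (sig["p"] < 0.05).all()

    def test_t_matches_closed_form_welch_oracle(self):
        rng = np.random.default_rng(12)
        a = _block(_random_rows(7, 4, rng), "A")
        b = _block(_random_rows(9, 4, rng), "B")
        res = two_sample_logo(a, b)
        for _, row in res.table.iterrows():
            xa = [1.0 if c == row["residue"] else 0.0 for c in a.column(row["column"])]
            xb = [1.0 if c == row["residue"] else 0.0 for c in b.column(row["column"])]
            assert row["t"] == pytest.approx(welch_oracle(xa, xb), abs=1e-9)

    def test_matches_scipy_when_variances_are_positive(self):
        a = _block(["C", "C", "C", "E", "E"], "A")
        b = _block(["C", "E", "E", "E"], "B")
        res = two_sample_logo(a, b)
        row = res.table[(res.table["residue"] == "C") & (res.table["column"] == 0)].iloc[0]
        xa = [1, 1, 1, 0, 0]
        xb = [1, 0, 0, 0]
        ref = sps.ttest_ind(xa, xb, equal_var=False)
        assert row["t"] == pytest.approx(ref.statistic, abs=1e-6)
        assert row["p"] == pytest.approx(ref.pvalue, abs=1e-6)

    def test_symmetric_under_group_swap_with_direction_flip(self):
        rng = np.random.default_rng(4)
        a = _block(_random_rows(5, 3, rng), "A")
        b = _block(_random_rows(6, 3, rng), "B")
        fwd = two_sample_logo(a, b).table
        rev = two_sample_logo(b, a).table
        assert np.allclose(fwd["t"], -rev["t"], atol=1e-12)
        assert np.allclose(fwd["p"], rev["p"], atol=1e-12)
        flip = {"enriched": "depleted", "depleted": "enriched", "none": "none"}
        assert [flip[d] for d in fwd["direction"]] == list(rev["direction"])

    def test_bonferroni_is_more_conservative(self):
        a = _block(["C", "C", "C", "E"], "A")
        b = _block(["E", "E", "E", "C"], "B")
        plain = two_sample_logo(a, b).significant_cells()
        corrected = two_sample_logo(a, b, correction="bonferroni").significant_cells()
        assert len(corrected) <= len(plain)

    def test_subfamily_discriminating_residue_is_found(self):
        """Contrasting a CxxxHGH-bearing group with an ExxHGH-bearing group
        flags C vs E at the first motif position as the key residues."""
        rng = np.random.default_rng(21)
        a = TestConsensusMotif()._ptps_like_block("CxxHGH", n=10, flank=0, rng=rng)
        b = TestConsensusMotif()._ptps_like_block("ExxHGH", n=10, flank=0, rng=rng)
        res = two_sample_logo(a, b, alpha=0.05)
        sig = res.significant_cells()
        col0 = sig[sig["column"] == 0].set_index("residue")
        assert col0.loc["C", "direction"] == "enriched"
        assert col0.loc["E", "direction"] == "depleted"

    def test_group_too_small_is_an_error(self):
        with pytest.raises(ValueError):
            two_sample_logo(_block(["C", "C"]), _block(["E"], ids=("x",)))

    def test_width_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            two_sample_logo(_block(["CC", "CC"]), _block(["E", "E"]))


def test_meme_output_rows_are_probability_distributions(tmp_path):
    block = _block(["CHG", "CHG", "CEG", "CHG"])
    pfm = build_pfm(block)
    path = write_meme({"SG1": pfm}, tmp_path / "pfms.meme")
    text = path.read_text()
    assert "MOTIF SG1" in text
    matrix_lines = [
        l for l in text.splitlines() if l and l[0].isdigit()
    ]
    assert len(matrix_lines) == 3
    for line in matrix_lines:
        assert sum(float(x) for x in line.split()) == pytest.approx(1.0, abs=1e-4)
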