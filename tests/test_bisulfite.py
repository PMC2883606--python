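"""Bisulfite methylation calling, context classification, and summaries."""

import numpy as np
import pandas as pd
import pytest

from teloepi import synthetic as syn
from teloepi.bisulfite import (
    CALL_CONVERTED,
    CALL_METHYLATED,
    CALL_MISSING,
    BisulfiteRegion,
    align_clone,
    align_clones,
    classify_context,
    classify_region_contexts,
    compare_genotypes,
    conversion_check,
    matrix_diagram,
    summarize,
)
from teloepi.motif import reverse_complement


@pytest.fixture(scope="module")
def region():
    return syn.region_1l0()


def convert_all(seq: str) -> str:
    return seq.replace("C", "T")


class TestRegion:
    def test_unit_annotation_validated(self):
        with pytest.raises(ValueError, match="unit"):
            BisulfiteRegion("bad", "AAACCCTAAA", unit_starts=(0,))

    def test_control_positions_must_be_cytosines(self):
        with pytest.raises(ValueError, match="control"):
            BisulfiteRegion("bad", "CCCTAAA", unit_starts=(0,), control_positions=(3,))

    def test_repeat_cytosines_are_three_per_unit(self, region):
        assert len(region.repeat_cytosine_positions) == 3 * syn.N_UNITS_1L0
        for pos in region.repeat_cytosine_positions:
            assert region.sequence[pos] == "C"
            assert region.repeat_phase(pos) in (1, 2, 3)


class TestAlignClone:
    def test_unconverted_clone_is_fully_methylated(self, region):
        res = align_clone(region.sequence, region)
        assert not res.rejected
        assert set(res.calls.values()) == {CALL_METHYLATED}

    def test_fully_converted_clone_has_no_methylation(self, region):
        res = align_clone(convert_all(region.sequence), region)
        assert not res.rejected
        assert set(res.calls.values()) == {CALL_CONVERTED}

    def test_selected_positions_converted(self, region):
        targets = {region.repeat_cytosine_positions[0],
                   region.repeat_cytosine_positions[5]}
        seq = "".join(
            "T" if i in targets else b for i, b in enumerate(region.sequence)
        )
        res = align_clone(seq, region)
        for pos, call in res.calls.items():
            expected = CALL_CONVERTED if pos in targets else CALL_METHYLATED
            assert call == expected, pos

    def test_bottom_strand_clone_auto_reoriented(self, region):
        converted = convert_all(region.sequence)
        res = align_clone(reverse_complement(converted), region)
        assert not res.rejected
        assert res.reoriented
        assert set(res.calls.values()) == {CALL_CONVERTED}

    def test_clone_with_too_many_mismatches_rejected(self, region):
        seq = list(convert_all(region.sequence))
        # corrupt 8 non-cytosine reference positions (default max_mismatch 5)
        non_c = [i for i, b in enumerate(region.sequence) if b != "C"][:8]
        for i in non_c:
            seq[i] = {"A": "G", "T": "G", "G": "A"}[region.sequence[i]]
        res = align_clone("".join(seq), region)
        assert res.rejected
        assert "mismatch" in res.reason

    def test_truncated_clone_gets_missing_calls(self, region):
        res = align_clone(region.sequence[30:], region)
        assert not res.rejected
        missing = [p for p, c in res.calls.items() if c == CALL_MISSING]
        assert missing == [p for p in region.cytosine_positions if p < 30]

    def test_batch_rejects_reported_not_dropped(self, region):
        clones = [
            ("good", "wt", region.sequence),
            ("bad", "wt", "ACGT" * 30),
        ]
        matrix = align_clones(clones, region)
        assert matrix.n_clones == 1
        assert list(matrix.rejects["clone_id"]) == ["bad"]


class TestContext:
    def test_first_c_of_tandem_repeat_is_chh_phase_one(self):
        region = BisulfiteRegion("r", "CCCTAAACCCTAAA", unit_starts=(0, 7))
        call = classify_context(region, 0)
        assert (call.context, call.repeat_phase) == ("CHH", 1)

    def test_canonical_cg(self):
        region = BisulfiteRegion("r", "ACGT")
        assert classify_context(region, 1).context == "CG"

    def test_canonical_chg(self):
        region = BisulfiteRegion("r", "CAGT")
        assert classify_context(region, 0).context == "CHG"

    def test_edge_cytosine_without_downstream_is_na(self):
        region = BisulfiteRegion("r", "AAAC")
        assert classify_context(region, 3).context == "NA"

    def test_edge_cytosine_with_downstream_resolved(self):
        region = BisulfiteRegion("r", "AAAC", downstream_context="GT")
        assert classify_context(region, 3).context == "CG"

    def test_non_cytosine_rejected(self):
        region = BisulfiteRegion("r", "ACGT")
        with pytest.raises(ValueError):
            classify_context(region, 0)

    def test_pure_repeat_is_all_chh(self):
        region = BisulfiteRegion(
            "r", "CCCTAAA" * 5, unit_starts=tuple(range(0, 35, 7)),
            downstream_context="CC",
        )
        calls = classify_region_contexts(region)
        assert len(calls) == 15
        assert all(c.context == "CHH" for c in calls)
        assert [c.repeat_phase for c in calls] == [1, 2, 3] * 5

    def test_every_cytosine_gets_exactly_one_context(self, region):
        calls = classify_region_contexts(region)
        assert len(calls) == len(region.cytosine_positions)
        assert all(c.context in ("CG", "CHG", "CHH", "NA") for c in calls)


class TestSummarize:
    def test_all_methylated_gives_one_everywhere(self, region):
        clones = [(f"c{i}", "wt", region.sequence) for i in range(3)]
        s = summarize(align_clones(clones, region))
        assert s.overall == 1.0
        assert s.overall_repeat == 1.0
        assert all(s.per_phase == 1.0)

    def test_all_converted_gives_zero(self, region):
        clones = [(f"c{i}", "wt", convert_all(region.sequence)) for i in range(3)]
        s = summarize(align_clones(clones, region))
        assert s.overall == 0.0

    def test_estimate_within_binomial_band_of_truth(self, region):
        p = 0.45
        probs = {pos: p for pos in region.cytosine_positions}
        clones, _ = syn.simulate_bisulfite_clones(
            region, probs, conversion=1.0, n_clones=30, seed=17
        )
        s = summarize(align_clones(clones, region))
        n_cells = 30 * len(region.cytosine_positions)
        half_width = 1.96 * np.sqrt(p * (1 - p) / n_cells)
        assert abs(s.overall - p) < half_width * 1.5

    def test_call_counts_sum_to_clone_count(self, region):
        probs = syn.preset_probabilities(region, "wt-1L0")
        clones, _ = syn.simulate_bisulfite_clones(region, probs, 0.99, 12, seed=2)
        matrix = align_clones(clones, region)
        counts = matrix.calls.apply(pd.Series.value_counts).fillna(0)
        assert (counts.sum(axis=0) == matrix.n_clones).all()

    def test_empty_matrix_rejected(self, region):
        with pytest.raises(ValueError):
            summarize(align_clones([], region))


class TestConversionCheck:
    def test_full_conversion_passes(self, region):
        clones = [("c1", "wt", convert_all(region.sequence))]
        rate, status = conversion_check(align_clones(clones, region))
        assert rate == 1.0 and status == "pass"

    def test_ninety_percent_fails_default_threshold(self):
        # 10 control cytosines, 10 clones: one clone leaves 10 unconverted
        seq = "ACT" * 10 + "GGA"
        region = BisulfiteRegion(
            "ctrl", seq, control_positions=tuple(i for i, b in enumerate(seq) if b == "C")
        )
        clones = [(f"c{i}", "wt", convert_all(seq)) for i in range(9)]
        clones.append(("c9", "wt", seq))
        rate, status = conversion_check(align_clones(clones, region))
        assert rate == pytest.approx(0.90)
        assert status == "fail"

    def test_no_controls_reports_warning_status(self):
        region = BisulfiteRegion("r", "CCCTAAA", unit_starts=(0,))
        clones = [("c1", "wt", "CCCTAAA")]
        rate, status = conversion_check(align_clones(clones, region))
        assert rate is None and status == "no conversion control"

    def test_simulated_conversion_rate_recovered(self, region):
        probs = syn.preset_probabilities(region, "wt-1L0")
        clones, _ = syn.simulate_bisulfite_clones(region, probs, 0.99, 50, seed=23)
        rate, status = conversion_check(align_clones(clones, region))
        n_ctrl = 50 * len(region.control_positions)
        band = 3 * np.sqrt(0.99 * 0.01 / n_ctrl)
        assert abs(rate - 0.99) < band
        assert status == "pass"


class TestCompareGenotypes:
    def make_summary(self, region, preset, sample, n, seed):
        probs = syn.preset_probabilities(region, preset)
        clones, _ = syn.simulate_bisulfite_clones(
            region, probs, 0.99, n, seed=seed, sample=sample
        )
        return summarize(align_clones(clones, region))

    def test_identical_summaries_give_zero_differences(self, region):
        s = self.make_summary(region, "wt-1L0", "wt", 10, 4)
        table = compare_genotypes(s, s)
        assert (table["difference"] == 0).all()

    def test_wt_vs_rdr2_difference_near_construction(self, region):
        wt = self.make_summary(region, "wt-1L0", "wt", 30, 31)
        mut = self.make_summary(region, "rdr2-1L0", "rdr2", 19, 32)
        table = compare_genotypes(wt, mut).set_index("stratum")
        # true repeat-cytosine difference is 0.45 - 0.05 = 0.40
        diff = table.loc["overall_repeat", "difference"]
        assert diff == pytest.approx(0.40, abs=0.06)
        # phase-3 enrichment visible only in wild type
        assert table.loc["phase:3", "a"] > table.loc["phase:1", "a"] + 0.1

    def test_mismatched_regions_rejected(self, region):
        s = self.make_summary(region, "wt-1L0", "wt", 5, 6)
        other = BisulfiteRegion("other", "CCCTAAA" * 2, unit_starts=(0, 7))
        clones = [("c1", "wt", other.sequence)]
        s2 = summarize(align_clones(clones, other))
        with pytest.raises(ValueError):
            compare_genotypes(s, s2)


def test_matrix_diagram_rows_match_clones(region):
    probs = syn.preset_probabilities(region, "wt-1L0")
    clones, _ = syn.simulate_bisulfite_clones(region, probs, 1.0, 4, seed=8)
    matrix = align_clones(clones, region)
    diagram = matrix_diagram(matrix)
    lines = diagram.splitlines()
    assert len(lines) == 4
    assert all(set(line.split()[-1]) <= {"M", "c", "."} for line in lines)
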