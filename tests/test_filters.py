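"""Substitution and indel post-processing filter cascades."""

import dataclasses

import pytest

from renomics import (
    PanelSummary,
    VariantRecord,
    apply_cascade,
    filter_indel,
    filter_substitution,
    simulate_variant_records,
)
from renomics.filters import read_records_tsv
from renomics.simulate import KNOWN_RULE_IDS, _make_indel, _make_substitution

import numpy as np

PANEL = PanelSummary(100)


def clean_sub(**overrides):
    rec = _make_substitution(0, np.random.default_rng(0), frozenset())
    return dataclasses.replace(rec, **overrides)


def clean_indel(**overrides):
    rec = _make_indel(0, np.random.default_rng(0), frozenset())
    return dataclasses.replace(rec, **overrides)


class TestSubstitutionRules:
    def test_clean_record_passes(self):
        assert filter_substitution(clean_sub(), PANEL).passed

    def test_base_quality_third(self):
        # 1 of 6 mutant bases at BQ >= 25 is below a third
        rec = clean_sub(
            mutant_read_base_qualities=(26, 10, 10, 10, 10, 10),
            mutant_read_positions=(0.5, 0.5, 0.5, 0.5, 0.5, 0.5),
            mean_base_quality=12.67,
        )
        assert "base-quality-third" in filter_substitution(rec, PANEL).failed_rules

    def test_exactly_one_third_passes_quality_rule(self):
        # "at least a third" is inclusive: 2/6 qualifies
        rec = clean_sub(
            mutant_read_base_qualities=(26, 26, 10, 10, 10, 10),
            mutant_read_positions=(0.5,) * 6,
            mutant_coverage=6,
            mean_base_quality=15.33,
        )
        assert "base-quality-third" not in filter_substitution(rec, PANEL).failed_rules

    def test_middle_third_required_at_high_coverage(self):
        rec = clean_sub(mutant_read_positions=tuple([0.1] * 6 + [0.9] * 6))
        assert "middle-read-position" in filter_substitution(rec, PANEL).failed_rules

    def test_first_two_thirds_suffice_at_low_coverage(self):
        rec = clean_sub(
            mutant_coverage=6,
            mutant_read_base_qualities=(30,) * 6,
            mutant_read_positions=(0.1, 0.1, 0.2, 0.2, 0.9, 0.9),
        )
        assert "middle-read-position" not in filter_substitution(rec, PANEL).failed_rules

    def test_zero_normal_vaf_satisfies_contamination_rule(self):
        rec = clean_sub(matched_normal_vaf=0.0)
        assert "normal-contamination" not in filter_substitution(rec, PANEL).failed_rules

    def test_fivefold_rule_on_nonzero_normal(self):
        rec = clean_sub(matched_normal_vaf=0.05)  # tumor VAF 0.12 <= 5 x 0.05
        assert "normal-contamination" in filter_substitution(rec, PANEL).failed_rules
        ok = clean_sub(matched_normal_vaf=0.02)  # 0.12 > 0.10
        assert "normal-contamination" not in filter_substitution(ok, PANEL).failed_rules

    def test_strand_bias_only_below_mean_quality_20(self):
        biased = dict(strand_counts=(97, 3))
        armed = clean_sub(mean_base_quality=18.0, **biased)
        assert "strand-bias" in filter_substitution(armed, PANEL).failed_rules
        disarmed = clean_sub(mean_base_quality=30.0, **biased)
        assert "strand-bias" not in filter_substitution(disarmed, PANEL).failed_rules

    def test_region_flags_fail(self):
        rec = clean_sub(region_flags=frozenset({"centromeric"}))
        assert "region-mask" in filter_substitution(rec, PANEL).failed_rules

    def test_indel_record_rejected(self):
        with pytest.raises(TypeError):
            filter_substitution(clean_indel(), PANEL)

    def test_all_violated_rules_reported_not_just_first(self):
        rec = clean_sub(
            mutant_read_base_qualities=(10,) * 12,
            mutant_read_positions=(0.9,) * 12,
            matched_normal_vaf=0.5,
            region_flags=frozenset({"simple_repeat"}),
            mean_base_quality=10.0,
            strand_counts=(12, 0),
        )
        v = filter_substitution(rec, PANEL)
        assert set(v.failed_rules) >= {
            "base-quality-third", "middle-read-position",
            "normal-contamination", "strand-bias", "region-mask",
        }
        assert len(v.reasons) == len(v.failed_rules)


class TestIndelRules:
    def test_clean_record_passes(self):
        assert filter_indel(clean_indel(), PANEL).passed

    @pytest.mark.parametrize(
        "depth,vaf_reads,should_fail",
        [(150, 10, True),    # 6.7% < 8% below 200x
         (150, 12, False),   # 8% at depth < 200x
         (250, 12, False),   # 4.8% >= 4% at depth >= 200x
         (250, 9, True)],    # 3.6% < 4%
    )
    def test_depth_dependent_fraction(self, depth, vaf_reads, should_fail):
        rec = clean_indel(total_depth=depth, mutant_coverage=vaf_reads)
        failed = "min-allele-fraction" in filter_indel(rec, PANEL).failed_rules
        assert failed == should_fail

    def test_repeat_count_boundary(self):
        assert "small-repeat-count" not in filter_indel(
            clean_indel(small_repeat_count=9), PANEL
        ).failed_rules
        assert "small-repeat-count" in filter_indel(
            clean_indel(small_repeat_count=10), PANEL
        ).failed_rules

    def test_normal_or_panel_reads_fail(self):
        assert "normal-evidence" in filter_indel(
            clean_indel(matched_normal_reads=1), PANEL
        ).failed_rules
        assert "normal-evidence" in filter_indel(
            clean_indel(panel_hits=((1, 0.001),)), PANEL
        ).failed_rules

    def test_caller_support_disjunction(self):
        # no BWA reads is acceptable only with no repeats and both strands
        rec = clean_indel(bwa_mutant_reads=0, small_repeat_count=0, pindel_reads=(2, 3))
        assert "caller-support" not in filter_indel(rec, PANEL).failed_rules
        rec = clean_indel(bwa_mutant_reads=0, small_repeat_count=1, pindel_reads=(2, 3))
        assert "caller-support" in filter_indel(rec, PANEL).failed_rules
        rec = clean_indel(bwa_mutant_reads=0, small_repeat_count=0, pindel_reads=(5, 0))
        assert "caller-support" in filter_indel(rec, PANEL).failed_rules

    def test_sum_ms_threshold(self):
        assert "anchor-mapping-score" in filter_indel(
            clean_indel(sum_ms=149.0), PANEL
        ).failed_rules
        assert "anchor-mapping-score" not in filter_indel(
            clean_indel(sum_ms=150.0), PANEL
        ).failed_rules

    def test_substitution_record_rejected(self):
        with pytest.raises(TypeError):
            filter_indel(clean_sub(), PANEL)


class TestCascade:
    def test_all_clean_fixture_passes(self):
        records = [r for r, _ in simulate_variant_records(40, {}, seed=0)]
        _, summary = apply_cascade(records, PANEL)
        assert summary.attrs["n_pass"] == 40

    def test_verdicts_match_ground_truth_labels(self):
        mix = {rule: 0.3 for rule in KNOWN_RULE_IDS}
        labeled = simulate_variant_records(400, mix, seed=7)
        verdicts, _ = apply_cascade([r for r, _ in labeled], PANEL)
        for (rec, truth), v in zip(labeled, verdicts):
            assert set(v.failed_rules) == set(truth), rec.record_id

    def test_deterministic_under_reordering(self):
        labeled = simulate_variant_records(60, {"sub:region-mask": 0.5}, seed=2)
        recs = [r for r, _ in labeled]
        fwd, _ = apply_cascade(recs, PANEL)
        rev, _ = apply_cascade(recs[::-1], PANEL)
        assert {v.record_id: v.failed_rules for v in fwd} == {
            v.record_id: v.failed_rules for v in rev
        }

    def test_empty_input(self):
        verdicts, summary = apply_cascade([], PANEL)
        assert verdicts == [] and summary.attrs["n_records"] == 0

    def test_bed_masks_resolve_region_flags(self):
        rec = clean_sub(contig="1", position=1000, region_flags=frozenset())
        masks = {"simple_repeat": {"1": [(990, 1005)]}}  # 0-based half-open
        verdicts, _ = apply_cascade([rec], PANEL, masks=masks)
        assert "region-mask" in verdicts[0].failed_rules
        outside = {"simple_repeat": {"1": [(1000, 1005)]}}  # starts after pos0=999
        verdicts, _ = apply_cascade([rec], PANEL, masks=outside)
        assert verdicts[0].passed


def test_records_tsv_round_trip(tmp_path):
    import pandas as pd

    rows = [{
        "record_id": "r1", "contig": "1", "position": 500, "ref": "C", "alt": "T",
        "mutant_coverage": 12, "total_depth": 100,
        "mutant_read_base_qualities": "30,30,30",
        "mutant_read_positions": "0.4,0.5,0.6",
        "strand_counts": "2,1", "mean_base_quality": 30.0,
        "matched_normal_vaf": 0.0, "panel_hits": "1:0.01;2:0.02",
    }]
    path = tmp_path / "recs.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    [rec] = read_records_tsv(path)
    assert rec.mutant_read_base_qualities == (30.0, 30.0, 30.0)
    assert rec.panel_hits == ((1, 0.01), (2, 0.02))
    assert filter_substitution(rec, PANEL).passed
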