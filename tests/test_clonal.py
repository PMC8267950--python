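"""Ploidy annotation, gain/loss scoring, CNA calls and instability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mifish import (
    amplification_flags,
    annotate_ploidy,
    gain_loss_pattern,
    sample_summary,
)
from mifish.clonal import round_half_up_1dp, round_half_up_ratio

from conftest import make_records


class TestAnnotatePloidy:
    def test_tetraploid_major_clone(self, gene_panel):
        """The 8-4-4-4-3-2-4-5 clone annotates as tetraploid."""
        assert annotate_ploidy((8, 4, 4, 4, 3, 2, 4, 5), gene_panel).nucleus_ploidy == 4

    def test_uniform_diploid(self, panel):
        assert annotate_ploidy((2,) * 10, panel).nucleus_ploidy == 2

    def test_amplified_probe_excluded(self, panel):
        """A 20-copy amplification must not drag the average up."""
        ann = annotate_ploidy((20, 2, 2, 2, 2, 2, 2, 2, 2, 2), panel)
        assert ann.nucleus_ploidy == 2
        assert ann.excluded_probes == ("COX2",)

    def test_length_mismatch_rejected(self, panel):
        with pytest.raises(ValueError, match="panel size"):
            annotate_ploidy((2, 2), panel)

    def test_round_half_up_convention(self, gene_panel):
        # pooled mean 2.5 rounds up, not to even
        counts = (3, 3, 3, 3, 2, 2, 2, 2)
        assert annotate_ploidy(counts, gene_panel).nucleus_ploidy == 3


class TestRounding:
    @pytest.mark.parametrize(
        "num,den,expect",
        [(5, 2, 3), (3, 2, 2), (7, 2, 4), (9, 4, 2), (22, 10, 2)],
    )
    def test_half_up_integer(self, num, den, expect):
        assert round_half_up_ratio(num, den) == expect

    def test_half_up_one_decimal(self):
        assert round_half_up_1dp(215, 100) == 2.2  # 2.15 -> 2.2
        assert round_half_up_1dp(214, 100) == 2.1


class TestGainLossPattern:
    def test_isochromosome_8q_like_clone(self, gene_panel):
        """2-1-3-2-1-2-2-2 at ploidy 2: DBC2/CDH1 lost, MYC gained."""
        glp = gain_loss_pattern((2, 1, 3, 2, 1, 2, 2, 2), 2, gene_panel)
        assert glp.label(gene_panel.gene_names) == "MYC+,DBC2-,CDH1-"

    def test_tetraploid_clone_relative_calls(self, gene_panel):
        """8-4-4-4-3-2-4-5 at ploidy 4: COX2/ZNF217 gained, CDH1/TP53 lost."""
        glp = gain_loss_pattern((8, 4, 4, 4, 3, 2, 4, 5), 4, gene_panel)
        states = dict(zip(gene_panel.gene_names, glp.states))
        assert {g for g, s in states.items() if s == "gain"} == {"COX2", "ZNF217"}
        assert {g for g, s in states.items() if s == "loss"} == {"CDH1", "TP53"}

    def test_all_neutral_at_own_ploidy(self, gene_panel):
        glp = gain_loss_pattern((3,) * 8, 3, gene_panel)
        assert set(glp.states) == {"neutral"}

    @settings(max_examples=50, deadline=None)
    @given(counts=st.tuples(*[st.integers(1, 4)] * 8), k=st.sampled_from([1, 2]))
    def test_wgd_scaling_invariance(self, counts, k):
        """Doubling every count and the ploidy leaves the calls unchanged."""
        from mifish import DEFAULT_PANEL
        from mifish.panel import ProbePanel

        genes = ProbePanel([p for p in DEFAULT_PANEL if p.role == "gene"])
        base = gain_loss_pattern(counts, 2, genes)
        scaled = gain_loss_pattern(tuple(k * c for c in counts), 2 * k, genes)
        assert base.states == scaled.states


class TestSampleSummary:
    def test_case_7l_instability_and_class(self, case_7l_records, panel):
        """Five patterns over 250 nuclei give the cohort-minimum index of 2."""
        s = sample_summary(case_7l_records, panel)
        assert s.n_patterns == 5
        assert s.instability_index == pytest.approx(2.0)
        assert s.average_ploidy == 2.0
        assert s.ploidy_class == "diploid"
        assert s.major_clone_fraction == pytest.approx(217 / 250)

    def test_instability_formula_limits(self, panel):
        same = make_records([((2,) * 8, 80)])
        assert sample_summary(same, panel).instability_index == pytest.approx(100 / 80)
        distinct = make_records([((2 + i, 2, 2, 2, 2, 2, 2, 2), 1) for i in range(6)])
        assert sample_summary(distinct, panel).instability_index == pytest.approx(100)

    def test_instability_invariant_under_reordering(self, case_7l_records, panel):
        rng = np.random.default_rng(0)
        shuffled = list(case_7l_records)
        rng.shuffle(shuffled)
        assert (
            sample_summary(shuffled, panel).instability_index
            == sample_summary(case_7l_records, panel).instability_index
        )

    @pytest.mark.parametrize(
        "gain_nuclei,expected", [(10, "none"), (60, "gain_minor"), (90, "gain_major")]
    )
    def test_cna_fraction_thresholds(self, gain_nuclei, expected, panel):
        """MYC gain called at >=15% of nuclei, major at >=85%."""
        records = make_records(
            [((2, 2, 3, 2, 2, 2, 2, 2), gain_nuclei),
             ((2,) * 8, 100 - gain_nuclei)]
        )
        s = sample_summary(records, panel)
        assert s.cna_calls["MYC"].call == expected

    def test_cna_monotone_in_fraction(self, panel):
        """Raising the fraction of gained nuclei never removes the call."""
        seen = []
        for n_gain in range(10, 100, 10):
            records = make_records(
                [((2, 2, 4, 2, 2, 2, 2, 2), n_gain), ((2,) * 8, 100 - n_gain)]
            )
            seen.append(sample_summary(records, panel).cna_calls["MYC"].call)
        called = [c != "none" for c in seen]
        assert called == sorted(called)  # once called, stays called

    def test_aneuploid_cutoff_boundary(self, panel):
        # 50/50 diploid-tetraploid nuclei: average 3.0 -> aneuploid
        records = make_records([((2,) * 8, 50)]) + make_records(
            [((4,) * 8, 50)], centromeres=(4, 4)
        )
        s = sample_summary(records, panel)
        assert s.average_ploidy == 3.0
        assert s.ploidy_class == "aneuploid"

    def test_empty_sample_rejected(self, panel):
        with pytest.raises(ValueError):
            sample_summary([], panel)


class TestAmplification:
    def test_strict_doubling_threshold(self, panel):
        """Mean of 5 at ploidy 2 is amplified; mean of exactly 4 is not."""
        her2 = panel.index_of("HER2")
        vec_amp = [2] * 10
        vec_amp[her2] = 5
        records = make_records([(tuple(vec_amp[:8]), 10)])
        assert amplification_flags(records, panel, 2) == {"HER2"}
        vec_edge = [2] * 10
        vec_edge[her2] = 4
        records = make_records([(tuple(vec_edge[:8]), 10)])
        assert amplification_flags(records, panel, 2) == set()

    def test_tetraploid_baseline(self, panel):
        vec = [4] * 8
        vec[2] = 9  # MYC at 9 > 2*4
        records = make_records([(tuple(vec), 10)], centromeres=(4, 4))
        assert amplification_flags(records, panel, 4) == {"MYC"}
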