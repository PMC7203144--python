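"""Normalization, exclusion, fold-change and enrichment-call behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erdomains.enrichment import (
    NormalizationSpec,
    call_enriched,
    exclude_nonspecific,
    fold_changes,
    normalize,
    reduced_set,
    select_top_n,
)
from erdomains.synthetic_data import (
    bait_accession,
    classification_metrics,
    sheet_tubule_config,
    simulate_ip_experiment,
    vapb_config,
)

from conftest import make_matrix, two_bait_samples


def noise_free(seed=0, **kw):
    cfg = sheet_tubule_config(
        seed, noise_sd=0.0, antibody_effect_sd=0.0, dropout_quantile=0.0, **kw
    )
    return simulate_ip_experiment(cfg)


class TestNormalize:
    def test_median_step_undoes_a_global_sample_scaling(self):
        m, _ = noise_free()
        doubled = m.copy()
        doubled.values[:, 0] *= 2.0
        spec = NormalizationSpec(order=("median",))
        a = normalize(m, spec)
        b = normalize(doubled, spec)
        assert np.allclose(a.values, b.values, equal_nan=True, rtol=1e-12)

    def test_bait_step_is_identity_for_equal_bait_abundance(self):
        samples = two_bait_samples(baits=("A", "B"), antibodies=("ab1",))
        m = make_matrix([[5.0, 3.0], [7.0, 7.0]], accessions=["X", "BAIT"])
        spec = NormalizationSpec(
            median_center=False, bait_accessions={"A": "BAIT", "B": "BAIT"}
        )
        m.samples = samples
        out = normalize(m, spec)
        assert np.allclose(out.values, m.values)

    def test_bait_step_removes_antibody_multipliers_exactly_when_noise_free(self):
        m, truth = simulate_ip_experiment(
            sheet_tubule_config(
                3, noise_sd=0.0, antibody_effect_sd=0.5, dropout_quantile=0.0
            )
        )
        spec = NormalizationSpec(
            median_center=False,
            bait_accessions={b: bait_accession(b) for b in ("Climp63", "DP1")},
        )
        out = normalize(m, spec)
        fc = fold_changes(out, "Climp63", "DP1")
        sheet = sorted(truth.members("sheet"))
        for col in fc.fc_columns:
            vals = fc.data.set_index("accession")[col][sheet]
            assert np.allclose(vals, 2.0, atol=1e-9)

    def test_missing_bait_in_own_ip_is_an_error(self):
        samples = two_bait_samples(baits=("A", "B"), antibodies=("ab1",))
        m = make_matrix([[5.0, 3.0], [np.nan, 7.0]], accessions=["X", "BAIT"])
        m.samples = samples
        spec = NormalizationSpec(
            median_center=False, bait_accessions={"A": "BAIT", "B": "BAIT"}
        )
        with pytest.raises(ValueError, match="cannot bait-normalize"):
            normalize(m, spec)

    def test_step_order_recorded_in_log(self):
        m, _ = noise_free()
        spec = NormalizationSpec()
        out = normalize(m, spec)
        assert any(step.startswith("normalize:median") for step in out.log)


class TestExcludeNonspecific:
    def make_with_controls(self, values, accessions):
        samples = two_bait_samples(
            baits=("A", "B"), antibodies=("ab1",), controls=True
        )
        m = make_matrix(np.asarray(values, dtype=float), accessions=accessions)
        m.samples = samples
        return m

    def test_protein_present_only_in_control_is_excluded(self):
        # columns: A-IP, B-IP, control
        m = self.make_with_controls(
            [[np.nan, np.nan, 50.0], [10.0, 10.0, np.nan]], ["CTRLONLY", "KEEP"]
        )
        spec = NormalizationSpec(low_abundance_quantile=0.0)
        out = exclude_nonspecific(m, spec)
        assert list(out.accessions) == ["KEEP"]

    def test_protein_absent_from_all_controls_is_retained(self):
        m = self.make_with_controls(
            [[10.0, 10.0, np.nan], [10.0, 10.0, 0.0]], ["P1", "P2"]
        )
        spec = NormalizationSpec(low_abundance_quantile=0.0)
        out = exclude_nonspecific(m, spec)
        assert set(out.accessions) == {"P1", "P2"}

    def test_control_fraction_threshold(self):
        # control carries 60% of the IP signal for P1, 10% for P2
        m = self.make_with_controls(
            [[10.0, 10.0, 6.0], [10.0, 10.0, 1.0]], ["P1", "P2"]
        )
        spec = NormalizationSpec(min_control_fraction=0.5, low_abundance_quantile=0.0)
        out = exclude_nonspecific(m, spec)
        assert list(out.accessions) == ["P2"]

    def test_simulated_background_mostly_excluded_under_defaults(self):
        rates = []
        for seed in (0, 1, 2):
            m, truth = simulate_ip_experiment(sheet_tubule_config(seed))
            out = exclude_nonspecific(m, NormalizationSpec())
            kept = set(out.accessions)
            bg = truth.members("background")
            rates.append(1 - len(kept & bg) / len(bg))
        assert np.mean(rates) >= 0.95

    def test_planted_classes_survive_the_control_filter(self):
        m, truth = simulate_ip_experiment(sheet_tubule_config(0))
        out = exclude_nonspecific(m, NormalizationSpec())
        kept = set(out.accessions)
        sheet = truth.members("sheet")
        assert len(kept & sheet) / len(sheet) > 0.9

    def test_no_controls_is_an_error(self):
        m = make_matrix([[1.0, 2.0]], accessions=["P1"])
        with pytest.raises(ValueError, match="control"):
            exclude_nonspecific(m, NormalizationSpec())


class TestFoldChanges:
    def test_toy_ratios(self):
        samples = two_bait_samples(baits=("A", "B"), antibodies=("ab1",))
        m = make_matrix([[4.0, 1.0], [2.0, 2.0], [np.nan, 8.0]])
        m.samples = samples
        fc = fold_changes(m, "A", "B")
        col = fc.data["log2fc_ab1"]
        assert col[0] == 2.0
        assert col[1] == 0.0
        assert np.isnan(col[2])  # missing side -> missing FC, no imputation

    def test_zero_abundance_gives_missing_not_infinite(self):
        samples = two_bait_samples(baits=("A", "B"), antibodies=("ab1",))
        m = make_matrix([[4.0, 0.0]])
        m.samples = samples
        fc = fold_changes(m, "A", "B")
        assert np.isnan(fc.data["log2fc_ab1"][0])

    def test_antibody_present_for_one_bait_is_skipped_with_warning(self):
        samples = [
            s for s in two_bait_samples(baits=("A", "B"), antibodies=("ab1", "ab2"))
            if not (s.bait == "B" and s.antibody == "ab2")
        ]
        m = make_matrix(np.ones((2, len(samples))))
        m.samples = samples
        with pytest.warns(UserWarning, match="ab2"):
            fc = fold_changes(m, "A", "B")
        assert fc.antibodies == ("ab1",)

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=1e-3, max_value=1e6),
                st.floats(min_value=1e-3, max_value=1e6),
            ),
            min_size=1,
            max_size=12,
        )
    )
    def test_fold_changes_are_antisymmetric(self, pairs):
        samples = two_bait_samples(baits=("A", "B"), antibodies=("ab1",))
        m = make_matrix(np.array(pairs, dtype=float))
        m.samples = samples
        ab = fold_changes(m, "A", "B").data["log2fc_ab1"].to_numpy()
        ba = fold_changes(m, "B", "A").data["log2fc_ab1"].to_numpy()
        # antisymmetric to the last ulp of log2(a/b); exact-power-of-two
        # ratios (the closed-form cases) negate bit-exactly
        assert np.allclose(ab, -ba, rtol=0, atol=1e-12, equal_nan=True)


class TestCallEnriched:
    def two_rep_fc(self, fcs_rep1, fcs_rep2):
        samples = two_bait_samples(
            baits=("A", "B"), antibodies=("ab1",), reps=(1, 2)
        )
        n = len(fcs_rep1)
        vals = np.empty((n, 4))
        # columns: A.ab1.r1, A.ab1.r2, B.ab1.r1, B.ab1.r2
        vals[:, 2:] = 1.0
        vals[:, 0] = np.exp2(fcs_rep1)
        vals[:, 1] = np.exp2(fcs_rep2)
        m = make_matrix(vals)
        m.samples = samples
        return fold_changes(m, "A", "B")

    def test_replicate_intersection_rule(self):
        fc = self.two_rep_fc([2.0, 2.0], [2.0, 0.0])
        ref = call_enriched(fc, tau=1.0, side="numerator")
        assert ref.members == {"P1"}  # P2 enriched in replicate 1 only

    def test_monotone_in_tau(self):
        m, _ = simulate_ip_experiment(sheet_tubule_config(0))
        fc = fold_changes(m, "Climp63", "DP1")
        members = [
            call_enriched(fc, tau, "numerator").members for tau in (0.5, 1.0, 1.5)
        ]
        assert members[2] <= members[1] <= members[0]

    def test_tau_above_max_effect_gives_empty_set(self):
        m, _ = noise_free()
        fc = fold_changes(m, "Climp63", "DP1")
        assert call_enriched(fc, tau=3.0, side="numerator").members == set()

    def test_noise_free_calls_recover_planted_classes_exactly(self):
        m, truth = noise_free()
        fc = fold_changes(m, "Climp63", "DP1")
        sheet = call_enriched(fc, 1.0, "numerator", name="sheet")
        tubule = call_enriched(fc, 1.0, "denominator", name="tubule")
        assert sheet.members == truth.members("sheet")
        assert tubule.members == truth.members("tubule")
        assert sheet.members.isdisjoint(tubule.members)

    def test_missing_fold_change_fails_the_threshold(self):
        fc = self.two_rep_fc([2.0], [np.nan])
        assert call_enriched(fc, 1.0, "numerator").members == set()

    def test_invalid_arguments(self):
        fc = self.two_rep_fc([2.0], [2.0])
        with pytest.raises(ValueError):
            call_enriched(fc, tau=0.0, side="numerator")
        with pytest.raises(ValueError):
            call_enriched(fc, tau=1.0, side="up")


class TestReducedSet:
    def fc_with_means(self, means_by_acc):
        samples = two_bait_samples(baits=("M", "W"), antibodies=("ab1", "ab2"))
        n = len(means_by_acc)
        vals = np.ones((n, 4))
        fcs = np.array(list(means_by_acc.values()))
        vals[:, 0] = np.exp2(fcs)  # M.ab1
        vals[:, 1] = np.exp2(fcs)  # M.ab2
        m = make_matrix(vals, accessions=list(means_by_acc))
        m.samples = samples
        return fold_changes(m, "M", "W")

    def test_cutoff_is_a_strict_inequality(self):
        fc = self.fc_with_means({"AT": -0.5, "BELOW": -0.5000001, "UP": 0.3})
        assert reduced_set(fc, cutoff=-0.5) == {"BELOW"}

    def test_all_zero_table_gives_empty_set(self):
        fc = self.fc_with_means({"P1": 0.0, "P2": 0.0})
        assert reduced_set(fc) == set()

    def test_simulated_reduction_recall_and_false_positives(self):
        recalls, fprs = [], []
        for seed in range(5):
            cfg = vapb_config(seed, tubule_reduction=0.5)
            m, truth = simulate_ip_experiment(cfg)
            fc = fold_changes(normalize(m, NormalizationSpec()), "VAPB-P56S", "VAPB-wt")
            red = reduced_set(fc, cutoff=-0.5)
            tub, sht = truth.members("tubule"), truth.members("sheet")
            recalls.append(len(red & tub) / len(tub))
            fprs.append(len(red & sht) / len(sht))
        assert np.mean(recalls) >= 0.9
        assert np.mean(fprs) <= 0.1


class TestSelectTopN:
    def abundance_toy(self):
        samples = two_bait_samples(baits=("A", "B"), antibodies=("ab1",))
        vals = np.array(
            [[50.0, 1], [40.0, 1], [30.0, 1], [20.0, 1], [10.0, 1]]
        )
        return make_matrix(
            vals,
            accessions=["P1", "P2", "P3", "P4", "P5"],
            genes=["g1", "g2", "g3", "g4", "g5"],
        ), samples

    def test_top_n_by_mean_abundance(self):
        m, samples = self.abundance_toy()
        m.samples = samples
        assert select_top_n(m, "A", 3) == ["g1", "g2", "g3"]

    def test_subtraction_happens_after_ranking(self):
        m, samples = self.abundance_toy()
        m.samples = samples
        # P1 removed after taking the top 3 -> list is shorter, P4 NOT pulled in
        assert select_top_n(m, "A", 3, subtract={"P1"}) == ["g2", "g3"]

    def test_ties_broken_by_accession(self):
        samples = two_bait_samples(baits=("A", "B"), antibodies=("ab1",))
        m = make_matrix(
            np.array([[5.0, 1], [5.0, 1], [5.0, 1]]),
            accessions=["PB", "PA", "PC"],
            genes=["gb", "ga", "gc"],
        )
        m.samples = samples
        assert select_top_n(m, "A", 2) == ["ga", "gb"]

    def test_n_exceeding_available_warns_and_returns_all(self):
        m, samples = self.abundance_toy()
        m.samples = samples
        with pytest.warns(UserWarning, match="only 5"):
            out = select_top_n(m, "A", 10)
        assert len(out) == 5


def test_pipeline_output_invariant_to_protein_row_order():
    m, truth = simulate_ip_experiment(sheet_tubule_config(4))
    perm = np.random.default_rng(0).permutation(len(m.proteins))
    shuffled = m.subset_proteins(perm)
    spec = NormalizationSpec()
    ref_a = call_enriched(
        fold_changes(normalize(m, spec), "Climp63", "DP1"), 1.0, "numerator"
    )
    ref_b = call_enriched(
        fold_changes(normalize(shuffled, spec), "Climp63", "DP1"), 1.0, "numerator"
    )
    assert ref_a.members == ref_b.members
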