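import numpy as np
import pandas as pd
import pytest

from loocomp import (
    FeatureGroupMap,
    FoldChangeSpec,
    SimulationConfig,
    aggregate,
    concat_timepoints,
    log2_fold_change,
    simulate_clinical,
    simulate_cohort,
    simulate_functional_profiles,
    to_relative,
)
from loocomp.differential import paired_subjects
from loocomp.profiles import ValidationError
from loocomp.simulate import CovariateTrend


class TestSimulateCohort:
    def test_design_sizes_and_nesting(self):
        tables, metadata, _ = simulate_cohort(SimulationConfig(seed=0))
        sizes = metadata.frame["timepoint"].value_counts()
        assert (sizes["baseline"], sizes["3MO"], sizes["1Y"]) == (13, 12, 8)
        subj = {
            tp: set(metadata.samples_at(tp)["subject_id"])
            for tp in ("baseline", "3MO", "1Y")
        }
        assert subj["1Y"] <= subj["3MO"] <= subj["baseline"]

    def test_deterministic_limit_profiles_identical_over_time(self):
        cfg = SimulationConfig(
            seed=5, n_taxa=10, noise_sd=0.0, subject_effect_sd=0.0,
            spike_taxa=(), bimodal_taxon=None, read_depth=0,
        )
        tables, metadata, _ = simulate_cohort(cfg)
        rel = to_relative(concat_timepoints(tables))
        for subject in paired_subjects(metadata, "baseline", "3MO"):
            p1 = rel.data.loc[metadata.sample_for(subject, "baseline")]
            p2 = rel.data.loc[metadata.sample_for(subject, "3MO")]
            np.testing.assert_allclose(p1.values, p2.values, rtol=1e-12)

    def test_two_taxon_closure_arithmetic(self):
        """delta=4 on one of two equal taxa: shares move 0.5->0.8 and 0.5->0.2."""
        cfg = SimulationConfig(
            seed=1, n_taxa=2, taxon_log_mean_sd=0.0, noise_sd=0.0,
            subject_effect_sd=0.0, spike_taxa=("taxon_000",), spike_delta=4.0,
            bimodal_taxon=None, unannotated_fraction=0.0,
        )
        tables, metadata, _ = simulate_cohort(cfg)
        rel3 = to_relative(tables["3MO"])
        relb = to_relative(tables["baseline"])
        assert np.allclose(relb.data["taxon_000"], 0.5)
        assert np.allclose(rel3.data["taxon_000"], 0.8)  # 4 / (4 + 1)
        assert np.allclose(rel3.data["taxon_001"], 0.2)

    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(seed=42, n_taxa=20, read_depth=5000)
        t1, m1, g1 = simulate_cohort(cfg)
        t2, m2, g2 = simulate_cohort(cfg)
        for tp in t1:
            pd.testing.assert_frame_equal(t1[tp].data, t2[tp].data)
        pd.testing.assert_frame_equal(m1.frame, m2.frame)
        pd.testing.assert_frame_equal(g1.effects, g2.effects)

    def test_exact_proportions_sum_to_one_minus_unannotated(self):
        cfg = SimulationConfig(seed=3, n_taxa=30, unannotated_fraction=0.2)
        tables, _, _ = simulate_cohort(cfg)
        rel = to_relative(concat_timepoints(tables))
        np.testing.assert_allclose(rel.data.sum(axis=1), 0.8, atol=1e-12)

    def test_ground_truth_effects(self):
        cfg = SimulationConfig(
            seed=2, n_taxa=10, spike_taxa=("taxon_003",), spike_delta=4.0,
            spike_persistent=True,
        )
        _, _, truth = simulate_cohort(cfg)
        assert truth.effect("taxon_003", "baseline->3MO") == 4.0
        assert truth.effect("taxon_003", "baseline->1Y") == 4.0
        assert truth.effect("taxon_003", "3MO->1Y") == 1.0
        assert (truth.effects.drop(index="taxon_003") == 1.0).all().all()

    def test_transient_spike_reverts(self):
        cfg = SimulationConfig(
            seed=2, n_taxa=10, spike_taxa=("taxon_003",), spike_delta=4.0,
            spike_persistent=False,
        )
        _, _, truth = simulate_cohort(cfg)
        assert truth.effect("taxon_003", "baseline->1Y") == 1.0
        assert truth.effect("taxon_003", "3MO->1Y") == 0.25

    def test_bimodal_taxon_has_two_modes(self):
        cfg = SimulationConfig(
            seed=9, n_taxa=20, bimodal_taxon="taxon_000",
            bimodal_high_fraction=0.5, bimodal_high_shift=6.0, noise_sd=0.1,
        )
        tables, _, _ = simulate_cohort(cfg)
        rel = to_relative(tables["baseline"])
        x = np.log10(rel.data["taxon_000"] + 1e-12)
        spread = x.max() - x.min()
        assert spread > 1.5  # orders of magnitude between modes

    def test_invalid_dropout_errors(self):
        with pytest.raises(ValidationError):
            SimulationConfig(dropout=(13, 8, 12))

    def test_multinomial_sampling_preserves_expectation(self):
        """Mean over resamples stays within 3 SE of the exact proportion."""
        cfg = SimulationConfig(seed=6, n_taxa=10, read_depth=0)
        tables, _, _ = simulate_cohort(cfg)
        rel = to_relative(tables["baseline"])
        p_exact = rel.data.iloc[0].to_numpy()
        depth = 20000
        rng = np.random.default_rng(0)
        full = np.append(p_exact, 1 - p_exact.sum())
        draws = rng.multinomial(depth, full, size=1000)[:, :-1] / depth
        se = np.sqrt(p_exact * (1 - p_exact) / depth / 1000)
        assert np.all(np.abs(draws.mean(0) - p_exact) <= 3 * se + 1e-12)

    def test_spiked_taxa_recover_positive_fold_change(self):
        """Median per-subject log2 fold change of spiked taxa is positive in
        >= 95% of replicates at delta=4, noise_sd <= 0.3, n >= 12."""
        hits, total = 0, 0
        for rep in range(200):
            cfg = SimulationConfig(
                seed=50_000 + rep, n_taxa=30,
                spike_taxa=("taxon_005", "taxon_015"), spike_delta=4.0,
                noise_sd=0.3,
            )
            tables, metadata, _ = simulate_cohort(cfg)
            rel = to_relative(concat_timepoints(tables))
            spec = FoldChangeSpec.from_table(rel)
            subj = paired_subjects(metadata, "baseline", "3MO")
            s1 = [metadata.sample_for(s, "baseline") for s in subj]
            s2 = [metadata.sample_for(s, "3MO") for s in subj]
            for taxon in cfg.spike_taxa:
                _, med = log2_fold_change(
                    rel.data.loc[s1, taxon], rel.data.loc[s2, taxon], spec
                )
                total += 1
                hits += med > 0
        assert hits / total >= 0.95


class TestFunctionalProfiles:
    def test_identity_repertoire(self, tiny_raw_table):
        out = simulate_functional_profiles(
            tiny_raw_table, {"A": {"K1": 1.0}, "B": {"K2": 1.0}}
        )
        np.testing.assert_allclose(out.data["K1"], tiny_raw_table.data["A"])
        np.testing.assert_allclose(out.data["K2"], tiny_raw_table.data["B"])

    def test_shared_ko_sums(self, tiny_raw_table):
        out = simulate_functional_profiles(
            tiny_raw_table, {"A": {"K1": 1.0}, "B": {"K1": 1.0}}
        )
        np.testing.assert_allclose(
            out.data["K1"], tiny_raw_table.data.sum(axis=1)
        )

    def test_module_equals_sum_of_member_kos(self):
        rng = np.random.default_rng(14)
        import pandas as pd

        from loocomp import AbundanceTable

        data = pd.DataFrame(
            rng.random((5, 4)), index=[f"s{i}" for i in range(5)],
            columns=[f"t{j}" for j in range(4)],
        )
        taxa = AbundanceTable(data)
        rep = {
            f"t{j}": {f"K{k}": float(rng.integers(1, 4)) for k in range(6)}
            for j in range(4)
        }
        modules = FeatureGroupMap({f"K{k}": f"M{k % 2}" for k in range(6)})
        ko = simulate_functional_profiles(taxa, rep)
        mod = simulate_functional_profiles(taxa, rep, group_map=modules)
        for m in ("M0", "M1"):
            members = [k for k in ko.feature_ids if modules.group_of(k) == m]
            np.testing.assert_allclose(
                mod.data[m], ko.data[members].sum(axis=1), rtol=1e-12
            )

    def test_empty_repertoire_errors(self, tiny_raw_table):
        with pytest.raises(ValidationError):
            simulate_functional_profiles(tiny_raw_table, {"A": {}})


class TestSimulateClinical:
    def test_piecewise_trajectory_noise_free(self, paired_metadata):
        frame = paired_metadata.frame.copy()
        extra = pd.DataFrame(
            {
                "sample_id": [f"subj_{i:02d}_1Y" for i in range(1, 5)],
                "subject_id": [f"subj_{i:02d}" for i in range(1, 5)],
                "timepoint": ["1Y"] * 4,
            }
        )
        from loocomp.profiles import SampleMetadata

        meta = SampleMetadata(pd.concat([frame, extra], ignore_index=True))
        spec = {"bmi": CovariateTrend(42.0, -3.0, 0.0)}
        out = simulate_clinical(meta, spec, seed=0)
        by_tp = out.frame.groupby("timepoint")["bmi"].unique()
        assert by_tp["baseline"].tolist() == [42.0]
        assert by_tp["3MO"].tolist() == [33.0]
        assert by_tp["1Y"].tolist() == [33.0]

    def test_zero_slopes_constant(self, paired_metadata):
        out = simulate_clinical(
            paired_metadata, {"x": CovariateTrend(5.0, 0.0, 0.0)}, seed=1
        )
        assert (out.frame["x"] == 5.0).all()

    def test_mean_trajectory_recovers_slopes(self):
        """With noise, the sample-mean trajectory matches the slopes
        within Monte-Carlo error at n = 1000 subjects."""
        import pandas as pd

        from loocomp.profiles import SampleMetadata

        n = 1000
        rows = [
            {"sample_id": f"s{i}_{tp}", "subject_id": f"s{i}", "timepoint": tp}
            for i in range(n)
            for tp in ("baseline", "3MO", "1Y")
        ]
        meta = SampleMetadata(pd.DataFrame(rows))
        spec = {"y": CovariateTrend(10.0, -2.0, 0.5, baseline_sd=1.0, noise_sd=2.0)}
        out = simulate_clinical(meta, spec, seed=2)
        means = out.frame.groupby("timepoint")["y"].mean()
        se = 3 * (np.sqrt(1 + 4) / np.sqrt(n))
        assert means["baseline"] == pytest.approx(10.0, abs=se)
        assert means["3MO"] == pytest.approx(10.0 - 6.0, abs=se)
        assert means["1Y"] == pytest.approx(10.0 - 6.0 + 4.5, abs=se)

    def test_reserved_covariate_name_errors(self, paired_metadata):
        with pytest.raises(ValidationError):
            simulate_clinical(
                paired_metadata, {"timepoint": CovariateTrend(1.0, 0.0, 0.0)}
            )
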