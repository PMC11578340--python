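import json

import numpy as np
import pytest

from cfrag.end_motif import differential_motifs, extract_end_motifs, motif_id
from cfrag.fragment_io import FilterConfig, filter_fragments, read_fragment_frame
from cfrag.response_labeling import TumorMeasurement, recist_classify
from cfrag.synthetic import (
    GenerationError,
    GroundTruth,
    Reference,
    SizingError,
    SyntheticConfig,
    SyntheticConfigError,
    choose_ground_truth,
    depth_fraction_for_score_fold,
    simulate_cohort,
    simulate_fragments,
    simulate_reference,
    write_cohort,
)
from cfrag.tss_coverage import TssAnnotation, tss_score


class TestConfig:
    def test_valid_default(self):
        SyntheticConfig().validate()

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_chromosomes=0),
            dict(fragments_per_sample=-1),
            dict(tss_depletion_depth_fraction=1.5),
            dict(n_increased_motifs=200, n_decreased_motifs=100),
            dict(fragment_length_min=700),
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(SyntheticConfigError):
            SyntheticConfig(**kwargs).validate()


class TestReference:
    def test_tss_boundaries(self):
        cfg = SyntheticConfig(seed=2, n_chromosomes=1, chromosome_length=100_000, n_genes=20)
        ref = simulate_reference(cfg)
        assert len(ref.tss) == 20
        assert all(500 <= a.tss <= 99_500 for a in ref.tss)

    def test_tss_spacing(self):
        cfg = SyntheticConfig(seed=2, n_chromosomes=1, chromosome_length=50_000, n_genes=30)
        ref = simulate_reference(cfg)
        positions = sorted(a.tss for a in ref.tss)
        assert min(np.diff(positions)) >= 1000

    def test_deterministic(self, tmp_path):
        cfg = SyntheticConfig(seed=5, n_chromosomes=1, chromosome_length=20_000,
                              n_genes=5, n_expressed_genes=2)
        r1 = simulate_reference(cfg)
        r2 = simulate_reference(cfg)
        assert r1.sequences == r2.sequences
        assert r1.tss == r2.tss

    def test_sizing_error(self):
        # arithmetic oracle: 200 genes x 1000 bp spacing cannot fit in 10 kb
        cfg = SyntheticConfig(seed=0, n_chromosomes=1, chromosome_length=10_000, n_genes=200)
        with pytest.raises(SizingError):
            simulate_reference(cfg)

    def test_uniformish_composition(self):
        cfg = SyntheticConfig(seed=3, n_chromosomes=1, chromosome_length=100_000,
                              n_genes=5, n_expressed_genes=2)
        ref = simulate_reference(cfg)
        seq = ref.sequences["chr1"]
        for base in "ACGT":
            assert seq.count(base) / len(seq) == pytest.approx(0.25, abs=0.01)


class TestGroundTruth:
    def test_motif_set_structure(self, small_reference, small_config):
        truth = choose_ground_truth(small_reference, small_config)
        assert len(truth.increased_motif_set) == small_config.n_increased_motifs
        assert len(truth.decreased_motif_set) == small_config.n_decreased_motifs
        assert not set(truth.increased_motif_set) & set(truth.decreased_motif_set)
        assert all(m[0] in "AG" for m in truth.increased_motif_set)
        assert all(m[0] == "C" for m in truth.decreased_motif_set)

    def test_labels_cover_every_sample(self, small_truth, small_config):
        labels = small_truth.per_sample_labels
        assert len(labels) == small_config.n_responders + small_config.n_nonresponders
        assert sum(v == "responder" for v in labels.values()) == small_config.n_responders

    def test_unrealizable_motif_raises(self, small_config):
        # genome of pure A cannot realize any C/G-containing motif
        ref = Reference(sequences={"chr1": "A" * 100_000}, tss=[])
        with pytest.raises(GenerationError, match="absent"):
            choose_ground_truth(ref, small_config)

    def test_realizability_in_both_groups(self, small_reference, small_truth, small_config):
        for label, seed in (("responder", 1), ("non-responder", 2)):
            frame = simulate_fragments(small_reference, small_truth, label, small_config, seed)
            kept, _ = filter_fragments(frame, FilterConfig())
            prof = extract_end_motifs(kept, small_reference.sequences)
            for m in small_truth.increased_motif_set + small_truth.decreased_motif_set:
                assert prof.count_of(m) > 0, (label, m)


class TestFragments:
    def test_lengths_truncated(self, small_reference, small_truth, small_config):
        frame = simulate_fragments(small_reference, small_truth, "responder", small_config, 7)
        clean, _ = filter_fragments(frame, FilterConfig())  # drop injected failures
        sizes = clean.insert_size
        assert sizes.min() >= 50 and sizes.max() <= 599

    def test_deterministic_under_seed(self, small_reference, small_truth, small_config):
        f1 = simulate_fragments(small_reference, small_truth, "responder", small_config, 99)
        f2 = simulate_fragments(small_reference, small_truth, "responder", small_config, 99)
        assert np.array_equal(f1.start, f2.start) and np.array_equal(f1.end, f2.end)

    def test_filter_fail_minority_per_rule(self, small_reference, small_truth):
        cfg = SyntheticConfig(
            seed=11, n_chromosomes=1, chromosome_length=100_000, n_genes=20,
            n_expressed_genes=4, n_responders=4, n_nonresponders=4,
            fragments_per_sample=5_000, filter_fail_fraction=0.02,
        )
        frame = simulate_fragments(small_reference, small_truth, "responder", cfg, 3)
        _, stats = filter_fragments(frame, FilterConfig())
        expected = int(round(0.02 * 5_000))
        for rule, count in stats.removed_by_rule.items():
            assert count == expected, rule

    def test_no_depletion_when_fraction_one(self, small_reference, small_truth):
        cfg = SyntheticConfig(
            seed=11, n_chromosomes=1, chromosome_length=100_000, n_genes=20,
            n_expressed_genes=4, n_responders=4, n_nonresponders=4,
            fragments_per_sample=60_000, tss_depletion_depth_fraction=1.0,
            filter_fail_fraction=0.0,
        )
        frame = simulate_fragments(small_reference, small_truth, "non-responder", cfg, 5)
        scores = [
            tss_score(frame, ann, 100_000).score
            for ann in small_reference.tss
            if ann.gene_id in small_truth.expressed_gene_set
        ]
        assert np.nanmean(scores) == pytest.approx(1.0, abs=0.12)

    def test_depletion_half_recovers_score_half(self):
        # short fragments make midpoint-thinning smearing negligible
        cfg = SyntheticConfig(
            seed=21, n_chromosomes=1, chromosome_length=100_000, n_genes=20,
            n_expressed_genes=6, n_responders=2, n_nonresponders=2,
            fragments_per_sample=150_000, fragment_length_mean=60,
            fragment_length_sd=5.0, fragment_length_min=50, fragment_length_max=80,
            tss_depletion_depth_fraction=0.5, filter_fail_fraction=0.0,
        )
        ref = simulate_reference(cfg)
        truth = choose_ground_truth(ref, cfg)
        scores = []
        for seed in range(10):
            frame = simulate_fragments(ref, truth, "non-responder", cfg, 1000 + seed)
            for ann in ref.tss:
                if ann.gene_id in truth.expressed_gene_set:
                    scores.append(tss_score(frame, ann, 100_000).score)
        assert np.nanmean(scores) == pytest.approx(0.5, abs=0.06)

    def test_null_motif_effect_vanishes_with_depth(self, small_reference, small_truth):
        cfg = SyntheticConfig(
            seed=11, n_chromosomes=1, chromosome_length=100_000, n_genes=20,
            n_expressed_genes=4, n_responders=4, n_nonresponders=4,
            fragments_per_sample=200_000, motif_effect_log2fc=0.0,
            tss_depletion_depth_fraction=1.0, filter_fail_fraction=0.0,
        )
        fa = simulate_fragments(small_reference, small_truth, "responder", cfg, 1)
        fb = simulate_fragments(small_reference, small_truth, "non-responder", cfg, 2)
        pa = extract_end_motifs(fa, small_reference.sequences)
        pb = extract_end_motifs(fb, small_reference.sequences)
        planted = small_truth.increased_motif_set + small_truth.decreased_motif_set
        lfc = [
            abs(np.log2(pb.frequency_of(m) / pa.frequency_of(m))) for m in planted
        ]
        assert max(lfc) < 0.15  # pure sampling noise at 400k ends

    def test_planted_motif_effect_recovered(self):
        # Monte-Carlo check of the generator against its own target:
        # group-mean log2 fc within [0.05, 0.15] for >= 9 of the 11
        # increased motifs, in each of 10 replicate seeds (6v6 groups).
        cfg = SyntheticConfig(
            seed=31, n_chromosomes=2, chromosome_length=200_000, n_genes=10,
            n_expressed_genes=0, n_responders=6, n_nonresponders=6,
            fragments_per_sample=200_000, motif_effect_log2fc=0.1,
            tss_depletion_depth_fraction=1.0, filter_fail_fraction=0.0,
        )
        ref = simulate_reference(cfg)
        truth = choose_ground_truth(ref, cfg)
        for seed in range(10):
            freq = {"responder": [], "non-responder": []}
            for g, group in enumerate(freq):
                for i in range(6):
                    frame = simulate_fragments(
                        ref, truth, group, cfg, 10_000 * seed + 100 * g + i
                    )
                    prof = extract_end_motifs(frame, ref.sequences)
                    freq[group].append(prof.frequencies)
            mean_r = np.mean(freq["responder"], axis=0)
            mean_n = np.mean(freq["non-responder"], axis=0)
            hits = 0
            for m in truth.increased_motif_set:
                lfc = np.log2(mean_n[motif_id(m)] / mean_r[motif_id(m)])
                hits += 0.05 <= lfc <= 0.15
            assert hits >= 9, f"seed {seed}: only {hits}/11 in window"

    def test_unknown_group_rejected(self, small_reference, small_truth, small_config):
        with pytest.raises(SyntheticConfigError):
            simulate_fragments(small_reference, small_truth, "maybe", small_config, 0)


class TestDepthFractionCalibration:
    def test_identity_at_one(self):
        assert depth_fraction_for_score_fold(1.0, SyntheticConfig()) == pytest.approx(1.0)

    def test_below_target_fold(self):
        cfg = SyntheticConfig()
        f = depth_fraction_for_score_fold(0.6, cfg)
        assert 0.3 < f < 0.6  # must overshoot the raw fraction to beat smearing


class TestCohort:
    def test_responder_tumors_shrink_ge_30(self):
        cfg = SyntheticConfig(seed=13, fragments_per_sample=500, n_genes=10,
                              n_expressed_genes=2, chromosome_length=50_000)
        bundle = simulate_cohort(cfg)
        clinical = bundle.clinical.set_index("patient_id")
        for pid, label in bundle.truth.per_sample_labels.items():
            row = clinical.loc[pid]
            m = TumorMeasurement(
                pid, row["initial_diameter_cm"], row["post_cycle2_diameter_cm"],
                bool(row["new_lesions"]),
            )
            recist = recist_classify(m)
            if label == "responder":
                assert recist.category in ("CR", "PR") and recist.responder
            else:
                assert recist.category in ("SD", "PD") and not recist.responder

    def test_identity_ratio_with_zero_noise(self):
        cfg = SyntheticConfig(
            seed=13, fragments_per_sample=500, n_genes=10, n_expressed_genes=2,
            chromosome_length=50_000, concentration_spike_fold_responder=1.0,
            noise_dispersion=0.0,
        )
        bundle = simulate_cohort(cfg)
        for series in bundle.concentrations:
            if bundle.truth.per_sample_labels[series.patient_id] == "responder":
                assert series.values["T2"] / series.values["T1"] == pytest.approx(1.0)

    def test_t3_reverts_to_baseline(self):
        cfg = SyntheticConfig(seed=13, fragments_per_sample=500, n_genes=10,
                              n_expressed_genes=2, chromosome_length=50_000,
                              noise_dispersion=0.0)
        bundle = simulate_cohort(cfg)
        for series in bundle.concentrations:
            assert series.values["T3"] == pytest.approx(series.values["T1"])

    def test_write_cohort_round_trips(self, tmp_path):
        cfg = SyntheticConfig(seed=17, fragments_per_sample=400, n_genes=8,
                              n_expressed_genes=2, chromosome_length=30_000,
                              n_responders=2, n_nonresponders=2)
        bundle = simulate_cohort(cfg)
        paths = write_cohort(bundle, tmp_path)
        truth = GroundTruth.from_dict(json.loads((tmp_path / "ground_truth.json").read_text()))
        assert truth == bundle.truth
        frame = read_fragment_frame(tmp_path / "fragments" / "R01.tsv")
        assert np.array_equal(frame.start, bundle.fragments["R01"].start)
        fasta = (tmp_path / "reference.fa").read_text()
        assert fasta.startswith(">chr1\n")

    def test_byte_identical_outputs(self, tmp_path):
        cfg = SyntheticConfig(seed=19, fragments_per_sample=300, n_genes=6,
                              n_expressed_genes=2, chromosome_length=20_000,
                              n_responders=2, n_nonresponders=2)
        write_cohort(simulate_cohort(cfg), tmp_path / "a")
        write_cohort(simulate_cohort(cfg), tmp_path / "b")
        for name in ("reference.fa", "tss.tsv", "clinical.tsv", "concentrations.tsv",
                     "ground_truth.json", "fragments/R01.tsv", "fragments/N02.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes(), name


class TestNullSafety:
    def test_false_positive_rate_near_alpha_without_lfc_gate(self):
        # with all effects neutral and lfc gate 0, direction calls are pure
        # p < alpha events: ~5% per motif (binomial check over 20 seeds)
        cfg = SyntheticConfig(
            seed=41, n_chromosomes=1, chromosome_length=100_000, n_genes=10,
            n_expressed_genes=0, n_responders=5, n_nonresponders=5,
            fragments_per_sample=10_000, motif_effect_log2fc=0.0,
            tss_depletion_depth_fraction=1.0, filter_fail_fraction=0.0,
            concentration_spike_fold_nonresponder=1.0,
            concentration_spike_fold_responder=1.0,
        )
        ref = simulate_reference(cfg)
        truth = choose_ground_truth(ref, cfg)
        rates = []
        for seed in range(20):
            profs = {"responder": [], "non-responder": []}
            for g, group in enumerate(profs):
                for i in range(5):
                    frame = simulate_fragments(ref, truth, group, cfg, 7_000 * seed + 10 * g + i)
                    profs[group].append(extract_end_motifs(frame, ref.sequences, sample_id=f"{g}{i}"))
            results = differential_motifs(
                profs["responder"], profs["non-responder"], lfc_threshold=0.0, alpha=0.05
            )
            rates.append(np.mean([r.direction != "none" for r in results]))
        mean_rate = float(np.mean(rates))
        # exact MWU at 5v5 is discrete: P(p < .05) is near but below .05
        assert 0.01 < mean_rate < 0.07, mean_rate
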