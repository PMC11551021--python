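"""Synthetic signal generator: pore model, read draws, signals, packs."""

import numpy as np
import pytest

from sigfilter import signalpack
from sigfilter.siggen import (
    LengthLaw,
    build_pore_model,
    generate_dataset,
    random_reference,
    reverse_complement,
    sample_reads_from_reference,
    simulate_read_signal,
)


class TestPoreModel:
    @pytest.mark.parametrize("k,expected", [(1, 4), (3, 64), (6, 4096)])
    def test_table_size_is_4_to_the_k(self, k, expected):
        assert build_pore_model(k=k, seed=42).level_mean.size == expected

    def test_identical_seed_gives_bitwise_identical_table(self):
        a = build_pore_model(k=6, seed=7)
        b = build_pore_model(k=6, seed=7)
        assert np.array_equal(a.level_mean, b.level_mean)
        assert not np.array_equal(a.level_mean,
                                  build_pore_model(k=6, seed=8).level_mean)

    @pytest.mark.parametrize("k", [0, 9, -3])
    def test_k_out_of_range_rejected(self, k):
        with pytest.raises(ValueError):
            build_pore_model(k=k, seed=1)

    def test_level_lookup_follows_lexicographic_order(self):
        pm = build_pore_model(k=2, seed=3)
        # AA is entry 0, AC entry 1, ..., TT entry 15
        assert pm.level_for("AA") == pm.level_mean[0]
        assert pm.level_for("CG") == pm.level_mean[4 + 2]
        assert pm.level_for("TT") == pm.level_mean[15]


class TestAdditivePoreModel:
    def test_table_shape_determinism_and_normalisation(self):
        from sigfilter.siggen import build_additive_pore_model

        a = build_additive_pore_model(k=6, seed=3)
        b = build_additive_pore_model(k=6, seed=3)
        assert a.level_mean.size == 4096
        assert np.array_equal(a.level_mean, b.level_mean)
        assert a.level_mean.std() == pytest.approx(1.0, rel=0.05)

    def test_additive_structure_explains_most_variance(self):
        """A per-position additive regression recovers ~1 - residual of
        the table variance."""
        from sigfilter.siggen import build_additive_pore_model

        pm = build_additive_pore_model(k=4, seed=9, residual=0.2)
        idx = np.arange(4**4)
        design = np.zeros((4**4, 16))
        for j in range(4):
            digit = (idx // 4 ** (3 - j)) % 4
            design[np.arange(4**4), j * 4 + digit] = 1.0
        coef, *_ = np.linalg.lstsq(design, pm.level_mean, rcond=None)
        r2 = 1 - ((pm.level_mean - design @ coef).var() / pm.level_mean.var())
        assert r2 == pytest.approx(0.8, abs=0.05)

    def test_invalid_residual_rejected(self):
        from sigfilter.siggen import build_additive_pore_model

        with pytest.raises(ValueError):
            build_additive_pore_model(k=3, seed=0, residual=1.5)


class TestReadSampling:
    def test_count_and_bounds(self, small_reference):
        draws = sample_reads_from_reference(
            small_reference, 5, LengthLaw.constant(500), seed=1)
        assert len(draws) == 5
        for d in draws:
            assert 0 <= d.start < d.end <= len(small_reference)
            assert len(d.sequence) == d.end - d.start == 500

    def test_minus_strand_is_reverse_complement(self, small_reference):
        draws = sample_reads_from_reference(
            small_reference, 50, LengthLaw.constant(300), seed=2)
        minus = [d for d in draws if d.strand == "-"]
        assert minus, "expected some minus-strand draws among 50"
        for d in minus[:5]:
            assert d.sequence == reverse_complement(
                small_reference[d.start:d.end])

    def test_same_seed_reproduces_draws(self, small_reference):
        a = sample_reads_from_reference(small_reference, 10,
                                        LengthLaw.lognormal(500), seed=5)
        b = sample_reads_from_reference(small_reference, 10,
                                        LengthLaw.lognormal(500), seed=5)
        assert [(d.sequence, d.start, d.strand) for d in a] == \
               [(d.sequence, d.start, d.strand) for d in b]

    def test_reference_shorter_than_min_length_rejected(self):
        with pytest.raises(ValueError):
            sample_reads_from_reference("ACGT" * 10, 3,
                                        LengthLaw.constant(100), seed=0)


class TestSignalSimulation:
    def test_noiseless_unit_dwell_k1_emits_exact_levels(self):
        pm = build_pore_model(k=1, seed=42, level_sd=0.0)
        rec = simulate_read_signal("ACG", pm, mean_dwell=1.0, seed=0)
        expected = [pm.level_for("A"), pm.level_for("C"), pm.level_for("G")]
        np.testing.assert_allclose(rec.samples, expected)
        assert rec.dwells.tolist() == [1, 1, 1]

    def test_sequence_shorter_than_k_rejected(self):
        pm = build_pore_model(k=6, seed=42)
        with pytest.raises(ValueError):
            simulate_read_signal("ACGTA", pm, seed=0)

    def test_noise_sd_matches_the_stated_law(self):
        # 10,000 emissions of a single k-mer: empirical sd within 5% of 0.2
        pm = build_pore_model(k=1, seed=42, level_sd=0.2)
        rec = simulate_read_signal("A" * 10_000, pm, mean_dwell=1.0, seed=3)
        sd = rec.samples.std()
        assert abs(sd - 0.2) / 0.2 < 0.05

    def test_expected_signal_length(self):
        # E[len] = (|seq| - k + 1) * mean_dwell; check within 3 SE over reads
        pm = build_pore_model(k=6, seed=42, level_sd=0.0)
        mean_dwell = 9.0
        seq_len, n = 106, 1000
        lengths = [
            simulate_read_signal(random_reference(seq_len, seed=i), pm,
                                 mean_dwell=mean_dwell, seed=i).samples.size
            for i in range(n)
        ]
        n_kmers = seq_len - 6 + 1
        expected = n_kmers * mean_dwell
        # per-position dwell variance is Poisson(mean_dwell - 1)
        se = np.sqrt(n_kmers * (mean_dwell - 1) / n)
        assert abs(np.mean(lengths) - expected) < 3 * se

    def test_truth_locus_length_must_match_sequence(self):
        pm = build_pore_model(k=1, seed=42)
        with pytest.raises(ValueError):
            simulate_read_signal("ACGT", pm, seed=0, truth_locus=(0, 3))


class TestGenerateDataset:
    def test_exact_on_target_allocation(self, pore_model_k6, target_refs,
                                        offtarget_refs):
        recs = generate_dataset(target_refs, offtarget_refs, 100, 0.3,
                                pore_model_k6,
                                length_law=LengthLaw.constant(300), seed=1)
        labels = [r.truth_label for r in recs]
        assert labels.count("on_target") == 30
        assert labels.count("off_target") == 70

    def test_target_fraction_zero_is_all_off_target(self, pore_model_k6,
                                                    offtarget_refs):
        recs = generate_dataset(None, offtarget_refs, 20, 0.0, pore_model_k6,
                                length_law=LengthLaw.constant(300), seed=1)
        assert all(r.truth_label == "off_target" for r in recs)

    def test_missing_required_references_rejected(self, pore_model_k6):
        with pytest.raises(ValueError):
            generate_dataset(None, None, 10, 0.5, pore_model_k6,
                             length_law=LengthLaw.constant(300), seed=1)

    def test_labels_equal_provenance(self, pore_model_k6, target_refs,
                                     offtarget_refs):
        recs = generate_dataset(target_refs, offtarget_refs, 40, 0.5,
                                pore_model_k6,
                                length_law=LengthLaw.constant(300), seed=2)
        for r in recs:
            expected = "on_target" if r.truth_source in target_refs else "off_target"
            assert r.truth_label == expected


class TestSignalPack:
    def test_round_trip_within_one_digitisation_step(self, pore_model_k6,
                                                     target_refs, tmp_path):
        recs = generate_dataset(target_refs, None, 10, 1.0, pore_model_k6,
                                length_law=LengthLaw.constant(300), seed=3,
                                out_dir=tmp_path / "pack")
        back = signalpack.read_pack(tmp_path / "pack")
        assert [r.read_id for r in back] == [r.read_id for r in recs]
        for orig, rt in zip(recs, back):
            assert np.abs(orig.samples - rt.samples).max() <= orig.scale
            assert rt.truth_seq == orig.truth_seq
            assert rt.truth_locus == orig.truth_locus
            assert np.array_equal(rt.dwells, orig.dwells)

    def test_manifest_read_ids_unique_and_matched(self, pore_model_k6,
                                                  target_refs, tmp_path):
        generate_dataset(target_refs, None, 25, 1.0, pore_model_k6,
                         length_law=LengthLaw.constant(300), seed=4,
                         out_dir=tmp_path / "pack")
        df = signalpack.read_manifest(tmp_path / "pack")
        assert df["read_id"].is_unique
        assert len(df) == 25
        blob = (tmp_path / "pack" / "signals.bin").stat().st_size
        assert blob == 2 * int(df["n_samples"].sum())

    def test_truncated_blob_fails_fast_with_read_id(self, pore_model_k6,
                                                    target_refs, tmp_path):
        generate_dataset(target_refs, None, 5, 1.0, pore_model_k6,
                         length_law=LengthLaw.constant(300), seed=5,
                         out_dir=tmp_path / "pack")
        blob = tmp_path / "pack" / "signals.bin"
        blob.write_bytes(blob.read_bytes()[:100])
        with pytest.raises(ValueError, match="read_00"):
            signalpack.read_pack(tmp_path / "pack")

    def test_subpack_is_byte_identical(self, pore_model_k6, target_refs,
                                       tmp_path):
        generate_dataset(target_refs, None, 8, 1.0, pore_model_k6,
                         length_law=LengthLaw.constant(300), seed=6,
                         out_dir=tmp_path / "pack")
        keep = ["read_000001", "read_000004"]
        signalpack.write_subpack(tmp_path / "pack", keep, tmp_path / "sub")
        orig = {r.read_id: r for r in signalpack.read_pack(tmp_path / "pack")}
        for rec in signalpack.read_pack(tmp_path / "sub"):
            assert np.array_equal(rec.samples, orig[rec.read_id].samples)
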