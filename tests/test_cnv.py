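import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methclass import cnv, datasets
from methclass.cnv import (
    CopyNumberSegmenter,
    call_segment_states,
    cohort_cnv_frequency,
    cohort_genomic_index,
    detect_focal_events,
    genomic_index,
    probe_log2_ratios,
    segment_cohort,
    segment_log2,
)


def _toy_annotation(n, chrom="chr1", spacing=1000):
    return pd.DataFrame(
        {"chrom": chrom, "pos": np.arange(1, n + 1) * spacing},
        index=pd.Index([f"p{i:04d}" for i in range(n)], name="probe_id"),
    )


class TestProbeLog2Ratios:
    def test_identical_sample_gives_zero(self):
        probes = [f"p{i}" for i in range(10)]
        ref = pd.DataFrame(100.0, index=probes, columns=["r1", "r2", "r3"])
        sample = pd.Series(100.0, index=probes)
        assert np.allclose(probe_log2_ratios(sample, ref), 0.0)

    def test_doubling_preserves_differences(self):
        ann = pd.concat([_toy_annotation(10, "chr1"), _toy_annotation(10, "chr2")])
        ann.index = [f"q{i}" for i in range(20)]
        ref = pd.DataFrame(200.0, index=ann.index, columns=["r1", "r2", "r3"])
        sample = pd.Series(np.where(ann["chrom"] == "chr1", 400.0, 200.0), index=ann.index)
        ratios = probe_log2_ratios(sample, ref)
        chr1 = ratios[ann["chrom"] == "chr1"]
        chr2 = ratios[ann["chrom"] == "chr2"]
        assert np.allclose(chr1.to_numpy() - chr2.to_numpy()[0], 1.0)

    def test_errors(self):
        probes = ["p1", "p2", "p3"]
        sample = pd.Series(1.0, index=probes)
        with pytest.raises(ValueError):
            probe_log2_ratios(sample, pd.DataFrame(1.0, index=probes, columns=["r1", "r2"]))
        bad_ref = pd.DataFrame(1.0, index=probes, columns=["r1", "r2", "r3"])
        bad_ref.iloc[0, 0] = 0.0
        with pytest.raises(ValueError):
            probe_log2_ratios(sample, bad_ref)

    def test_recovery_on_simulated_cohort(self, cohort, log2_ratios, filtered_beta):
        """Computed ratios track the true copy signal in CNV-loaded samples."""
        for sample in cohort.beta.columns:
            true = cohort.truth.log2[sample].loc[filtered_beta.index].to_numpy()
            if (true != 0).mean() >= 0.05:
                r = np.corrcoef(log2_ratios[sample].to_numpy(), true)[0, 1]
                assert r > 0.9


def _oracle_segment(values, min_probes=5, min_delta=0.1, alpha=0.01):
    """Exhaustive re-implementation of the split criterion via scipy."""
    breaks = []

    def recurse(lo, hi):
        candidates = list(range(lo + min_probes, hi - min_probes + 1))
        if not candidates:
            return
        best = None
        for k in candidates:
            t, p = stats.ttest_ind(values[k:hi], values[lo:k], equal_var=False)
            if best is None or abs(t) > abs(best[1]):
                best = (k, t, p, values[k:hi].mean() - values[lo:k].mean())
        k, _, p, delta = best
        if abs(delta) >= min_delta and p * len(candidates) < alpha:
            breaks.append(k)
            recurse(lo, k)
            recurse(k, hi)

    recurse(0, len(values))
    return sorted(breaks)


class TestSegmentation:
    def test_constant_signal_single_segment(self):
        ann = _toy_annotation(100)
        ratios = pd.Series(0.0, index=ann.index, name="s")
        segs = segment_log2(ratios, ann)
        assert len(segs) == 1
        assert segs.loc[0, "n_probes"] == 100

    def test_step_breakpoint_recovered(self):
        ann = _toy_annotation(100)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            values = np.where(np.arange(100) < 50, 0.0, 0.5) + rng.normal(0, 0.05, 100)
            segs = segment_log2(pd.Series(values, index=ann.index, name="s"), ann)
            if len(segs) == 2 and abs(segs.loc[1, "n_probes"] - 50) <= 2:
                hits += 1
        assert hits >= 19

    def test_matches_exhaustive_oracle(self):
        ann10 = _toy_annotation(10)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            values = np.where(np.arange(10) < rng.integers(3, 8), 0.0, 0.4)
            values = values + rng.normal(0, 0.05, 10)
            segs = segment_log2(pd.Series(values, index=ann10.index, name="s"), ann10,
                                min_probes=2)
            breaks = np.cumsum(segs["n_probes"].to_numpy())[:-1].tolist()
            assert breaks == _oracle_segment(values, min_probes=2)
        ann40 = _toy_annotation(40)
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            values = rng.normal(0, 0.1, 40)
            values[10:25] += rng.choice([-0.4, 0.4])
            segs = segment_log2(pd.Series(values, index=ann40.index, name="s"), ann40)
            breaks = np.cumsum(segs["n_probes"].to_numpy())[:-1].tolist()
            assert breaks == _oracle_segment(values)

    def test_rejects_unsorted_positions(self):
        ann = _toy_annotation(10)
        ann.loc[ann.index[3], "pos"] = 1  # break monotonicity
        with pytest.raises(ValueError):
            segment_log2(pd.Series(0.0, index=ann.index, name="s"), ann)

    def test_segment_means_reconstruct_probe_mean(self, log2_ratios, annotation, cohort_segments):
        """Probe-count-weighted mean of segment means equals the overall mean."""
        for sample in log2_ratios.columns[:10]:
            segs = cohort_segments[cohort_segments["sample_id"] == sample]
            weighted = (segs["mean_log2"] * segs["n_probes"]).sum() / segs["n_probes"].sum()
            assert weighted == pytest.approx(log2_ratios[sample].mean(), abs=1e-9)


class TestStateCalls:
    def test_boundary_is_balanced(self):
        segs = pd.DataFrame({"mean_log2": [0.1, -0.1, 0.3, -0.3, 0.0], "chrom": "chr1"})
        out = call_segment_states(segs)
        assert list(out["state"]) == ["balanced", "balanced", "gain", "loss", "balanced"]

    def test_rejects_bad_thresholds(self):
        with pytest.raises(ValueError):
            call_segment_states(pd.DataFrame({"mean_log2": [0.0]}), gain_thr=-0.1, loss_thr=-0.2)

    def test_probe_state_recovery_on_default_cohort(self, cohort, cohort_segments, filtered_beta, annotation):
        from methclass.methstats import probe_states_from_segments

        to_int = {"gain": 1, "balanced": 0, "loss": -1}
        correct = total = 0
        for sample in cohort.beta.columns:
            true = np.sign(cohort.truth.log2[sample].loc[filtered_beta.index].to_numpy())
            segs = cohort_segments[cohort_segments["sample_id"] == sample]
            called = probe_states_from_segments(annotation.loc[filtered_beta.index], segs)
            called = called.map(to_int).to_numpy()
            correct += int((called == true).sum())
            total += len(true)
        assert correct / total >= 0.95


class TestGenomicIndex:
    def test_formula_examples(self):
        segs = pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr2", "chr2", "chr3"],
             "state": ["gain", "loss", "gain", "gain", "balanced"]}
        )
        rec = genomic_index(segs)
        assert rec == {"n_altered_segments": 4, "n_involved_chromosomes": 2, "genomic_index": 8.0}
        balanced = pd.DataFrame({"chrom": ["chr1"], "state": ["balanced"]})
        assert genomic_index(balanced)["genomic_index"] == 0.0
        assert genomic_index(balanced)["n_involved_chromosomes"] == 0

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            n = int(rng.integers(1, 30))
            segs = pd.DataFrame(
                {"chrom": rng.choice([f"chr{i}" for i in range(1, 23)], n),
                 "state": rng.choice(["gain", "loss", "balanced"], n)}
            )
            rec = genomic_index(segs)
            a = sum(1 for s in segs["state"] if s != "balanced")
            chroms = {c for c, s in zip(segs["chrom"], segs["state"]) if s != "balanced"}
            expected = a * a / len(chroms) if a else 0.0
            assert rec["n_altered_segments"] == a
            assert rec["genomic_index"] == expected

    def test_invariant_under_relabeling_and_order(self):
        segs = pd.DataFrame({"chrom": ["chr1", "chr2", "chr2"], "state": ["gain", "loss", "gain"]})
        shuffled = segs.sample(frac=1, random_state=1)
        renamed = segs.assign(chrom=segs["chrom"].map({"chr1": "chrA", "chr2": "chrB"}))
        gi = genomic_index(segs)["genomic_index"]
        assert genomic_index(shuffled)["genomic_index"] == gi
        assert genomic_index(renamed)["genomic_index"] == gi

    def test_median_gi_orders_classes(self, cohort, cohort_segments):
        gi = cohort_genomic_index(cohort_segments)
        medians = gi.join(cohort.truth.classes)["genomic_index"].groupby(
            cohort.truth.classes
        ).median()
        assert medians["LG"] < medians["SARC"] < medians["PIS"]

    def test_median_gi_increases_with_cnv_rate(self, small_annotation):
        medians = []
        for rate in (1.0, 5.0, 15.0):
            per_seed = []
            for seed in range(10):
                spec = datasets.ClassSpec(label="S", n_samples=4, cnv_rate=rate, chr8_gain_prob=0.0)
                co = datasets.simulate_cohort(small_annotation, [spec], seed=seed)
                ratios = cnv.cohort_log2_ratios(
                    2.0 ** co.log2_intensity, 2.0 ** co.reference_log2_intensity
                )
                auto = small_annotation.index[~small_annotation["chrom"].isin(["chrX", "chrY"])]
                segs = segment_cohort(ratios.loc[auto], small_annotation)
                per_seed.append(cohort_genomic_index(segs)["genomic_index"].median())
            medians.append(np.median(per_seed))
        assert medians[0] < medians[1] < medians[2]


class TestCohortFrequency:
    def test_shared_chr8_gain_and_empty_cohort(self):
        segs = pd.DataFrame(
            {"sample_id": ["s1", "s2"], "chrom": "chr8", "start": 0, "end": 5000,
             "n_probes": 5, "mean_log2": 0.3, "state": "gain"}
        )
        freq = cohort_cnv_frequency(segs, bin_size=1000)
        assert (freq["gain_fraction"] == 1.0).all()
        balanced = segs.assign(state="balanced", mean_log2=0.0)
        freq0 = cohort_cnv_frequency(balanced, bin_size=1000)
        assert (freq0[["gain_fraction", "loss_fraction"]].to_numpy() == 0).all()
        with pytest.raises(ValueError):
            cohort_cnv_frequency(segs, bin_size=0)

    def test_matches_brute_force_overlap_count(self):
        rng = np.random.default_rng(7)
        rows = []
        for sample in ["s1", "s2", "s3"]:
            for _ in range(8):
                start = int(rng.integers(0, 90000))
                rows.append(
                    {"sample_id": sample, "chrom": rng.choice(["chr1", "chr2"]),
                     "start": start, "end": start + int(rng.integers(1000, 30000)),
                     "n_probes": 5, "mean_log2": 0.0,
                     "state": rng.choice(["gain", "loss", "balanced"])}
                )
        segs = pd.DataFrame(rows)
        bin_size = 7000
        freq = cohort_cnv_frequency(segs, bin_size, chrom_sizes={"chr1": 120000, "chr2": 120000})
        for _, row in freq.iterrows():
            for direction in ("gain", "loss"):
                count = 0
                for sample in ["s1", "s2", "s3"]:
                    hit = segs[
                        (segs["sample_id"] == sample) & (segs["chrom"] == row["chrom"])
                        & (segs["state"] == direction)
                        & (segs["start"] < row["end"]) & (segs["end"] > row["start"])
                    ]
                    count += int(len(hit) > 0)
                assert row[f"{direction}_fraction"] == pytest.approx(count / 3)


class TestFocalEvents:
    def test_examples(self):
        segs = pd.DataFrame(
            {"sample_id": ["s1", "s1"], "chrom": ["chr4", "chr8"],
             "start": [0, 0], "end": [100_000, 7_000_000],
             "n_probes": [20, 700], "mean_log2": [1.5, 0.3], "state": ["gain", "gain"]}
        )
        events = detect_focal_events(segs)
        assert len(events) == 1
        assert events.loc[0, "type"] == "amplification"
        assert events.loc[0, "chrom"] == "chr4"  # chromosome-level gain is not focal

    def test_matches_brute_force_threshold_scan(self):
        rng = np.random.default_rng(3)
        segs = pd.DataFrame(
            {"sample_id": "s1", "chrom": "chr1",
             "start": np.arange(50) * 10_000, "end": np.arange(1, 51) * 10_000,
             "n_probes": 5, "mean_log2": rng.normal(0, 0.8, 50), "state": "balanced"}
        )
        events = detect_focal_events(segs, amp_thr=0.9, del_thr=-0.9, max_len=50_000)
        expected = segs[(segs["mean_log2"].abs() > 0.9) & (segs["end"] - segs["start"] <= 50_000)]
        assert len(events) == len(expected)

    def test_gene_annotation(self):
        segs = pd.DataFrame(
            {"sample_id": ["s1"], "chrom": ["chr2"], "start": [5000], "end": [9000],
             "n_probes": [10], "mean_log2": [-2.0], "state": ["loss"]}
        )
        genes = pd.DataFrame(
            {"chrom": ["chr2", "chr2"], "start": [6000, 20000], "end": [7000, 21000],
             "gene_id": ["CDKN2A", "OTHER"]}
        )
        events = detect_focal_events(segs, gene_table=genes)
        assert events.loc[0, "type"] == "deep_deletion"
        assert events.loc[0, "genes"] == "CDKN2A"

    def test_rejects_thresholds_inside_call_band(self):
        with pytest.raises(ValueError):
            detect_focal_events(pd.DataFrame({"start": [], "end": [], "mean_log2": []}), amp_thr=0.05)


def test_seg_output_uses_one_based_inclusive(tmp_path, cohort_segments):
    path = tmp_path / "out.seg"
    cnv.write_seg(cohort_segments.head(5), path)
    seg = pd.read_csv(path, sep="\t")
    assert (seg["loc.start"] == cohort_segments.head(5)["start"].to_numpy() + 1).all()
    assert (seg["loc.end"] == cohort_segments.head(5)["end"].to_numpy()).all()


def test_segmenter_estimator_matches_functions(log2_ratios, annotation, cohort_segments):
    sub = log2_ratios.iloc[:, :3]
    est = CopyNumberSegmenter(annotation=annotation).fit(sub.T)
    expected = cohort_segments[cohort_segments["sample_id"].isin(sub.columns)].reset_index(drop=True)
    pd.testing.assert_frame_equal(est.segments_, expected)
    assert set(est.genomic_index_.index) == set(sub.columns)
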