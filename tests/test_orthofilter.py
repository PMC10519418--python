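import numpy as np
import pytest

from orthosweep.codon_align import CodonAlignment
from orthosweep.io_formats import OrthologCluster, SequenceRecord
from orthosweep.orthofilter import (
    FilterParams,
    FilterReport,
    distance_threshold_stats,
    occupancy_filter,
    occupancy_percent,
    pdistance_matrix,
    run_pipeline,
    step1_length_filter,
    step2_distance_filter,
    step3_missingness_filter,
    summarize_alignments,
)


def _cluster(lengths, cid="c1"):
    # sequences of sense codons "AAA" repeated; lengths in bases
    return OrthologCluster(
        cid,
        [
            SequenceRecord(f"s{i}", "AAA" * (n // 3), cid)
            for i, n in enumerate(lengths)
        ],
    )


class TestStep1:
    def test_five_percent_band(self):
        """Mean length 100 with a 5% cutoff: bounds 95-105, both extremes go."""
        cluster = _cluster([90, 102, 108])
        report = FilterReport()
        survivors = step1_length_filter(cluster, 5.0, report)
        assert [len(r) for r in survivors] == [102]
        steps = {r[1]: r[2] for r in report.rows}
        assert steps == {"s0": "length_set", "s2": "length_set"}

    def test_mean_is_original_single_pass(self):
        """300/300/600 at 30%: mean 400, bounds 280-520; only 600 removed."""
        survivors = step1_length_filter(_cluster([300, 300, 600]), 30.0)
        assert sorted(len(r) for r in survivors) == [300, 300]

    def test_iterate_reaches_fixed_point(self):
        """With iteration, the band is re-applied against the shrinking mean."""
        # single pass: mean 280, 30% band [196, 364] keeps 300s and 360
        cluster = _cluster([150, 300, 300, 360])
        single = step1_length_filter(cluster, 30.0)
        assert sorted(len(r) for r in single) == [300, 300, 360]
        iterated = step1_length_filter(cluster, 30.0, iterate=True)
        # second pass: mean 320, band [224, 416] -> unchanged fixed point
        assert sorted(len(r) for r in iterated) == [300, 300, 360]

    def test_prep_strips_gaps_and_terminal_ns(self):
        cluster = OrthologCluster(
            "c", [SequenceRecord("s0", "NNAC-GTAANN", "c"), SequenceRecord("s1", "ACGGTAAAA", "c")]
        )
        survivors = step1_length_filter(cluster, 100.0)
        assert {r.sample_id: r.sequence for r in survivors} == {
            "s0": "ACGTAA"[:6],
            "s1": "ACGGTAAAA",
        }

    def test_frame_and_stop_removed_at_prep(self):
        cluster = OrthologCluster(
            "c",
            [
                SequenceRecord("frame", "AAAA", "c"),  # length 4
                SequenceRecord("stop", "ATGTAAAAA", "c"),  # internal stop
                SequenceRecord("ok", "ATGAAAAAA", "c"),
            ],
        )
        report = FilterReport()
        survivors = step1_length_filter(cluster, 100.0, report)
        assert [r.sample_id for r in survivors] == ["ok"]
        reasons = {r[1]: r[3] for r in report.rows}
        assert reasons["frame"] == "not_multiple_of_three"
        assert reasons["stop"] == "internal_stop"


class TestPDistance:
    def test_simple_quarter(self):
        dm = pdistance_matrix({"x": "AAAA", "y": "AAAT"})
        assert dm.values[0, 1] == 25.0
        assert dm.compared_sites[0, 1] == 4

    def test_gap_and_n_sites_excluded(self):
        dm = pdistance_matrix({"x": "AA-AN", "y": "AAAAA"})
        assert dm.values[0, 1] == 0.0
        assert dm.compared_sites[0, 1] == 3

    def test_undefined_when_no_overlap(self):
        dm = pdistance_matrix({"x": "AANN", "y": "NNAA"})
        assert np.isnan(dm.values[0, 1])
        assert dm.compared_sites[0, 1] == 0

    def test_matches_columnwise_oracle(self, rng):
        rows = {
            f"s{i}": "".join(rng.choice(list("ACGTN-"), size=300)) for i in range(6)
        }
        dm = pdistance_matrix(rows)
        ids = list(rows)
        for i in range(6):
            for j in range(i + 1, 6):
                comp = mism = 0
                for a, b in zip(rows[ids[i]], rows[ids[j]]):
                    if a in "ACGT" and b in "ACGT":
                        comp += 1
                        mism += a != b
                assert dm.compared_sites[i, j] == comp
                if comp:
                    assert dm.values[i, j] == pytest.approx(100 * mism / comp)
                else:
                    assert np.isnan(dm.values[i, j])


class TestStep2:
    def test_outlier_removed_others_kept(self):
        """Three identical rows + one at 50%: outlier mean 50, rest 16.67."""
        base = "A" * 100
        far = "A" * 50 + "C" * 50
        aln = CodonAlignment({"a": base, "b": base, "c": base, "d": far}, [])
        report = FilterReport()
        survivors = step2_distance_filter(aln, 25.0, report, "c")
        assert survivors == ["a", "b", "c"]
        (row,) = [r for r in report.rows if r[1] == "d"]
        assert row[4] == pytest.approx(50.0)

    def test_identical_rows_nothing_removed(self):
        aln = CodonAlignment({"a": "ACGT", "b": "ACGT", "c": "ACGT"}, [])
        assert step2_distance_filter(aln, 0.0) == ["a", "b", "c"]

    def test_threshold_zero_is_strict(self):
        aln = CodonAlignment({"a": "AAAA", "b": "AAAT"}, [])
        assert step2_distance_filter(aln, 0.0) == []

    def test_small_instance_matches_bruteforce(self, rng):
        for _ in range(20):
            rows = {
                f"s{i}": "".join(rng.choice(list("ACGT"), size=60)) for i in range(6)
            }
            aln = CodonAlignment(rows, [])
            threshold = float(rng.uniform(10, 60))
            survivors = set(step2_distance_filter(aln, threshold))
            ids = list(rows)
            expected = set()
            for i in ids:
                ds = []
                for j in ids:
                    if i == j:
                        continue
                    comp = sum(1 for a, b in zip(rows[i], rows[j]))
                    mism = sum(a != b for a, b in zip(rows[i], rows[j]))
                    ds.append(100 * mism / comp)
                if np.mean(ds) <= threshold:
                    expected.add(i)
            assert survivors == expected


class TestStep3:
    @pytest.mark.parametrize(
        "n_missing, kept", [(26, False), (25, True), (0, True)]
    )
    def test_strict_boundary(self, n_missing, kept):
        row = "N" * n_missing + "A" * (100 - n_missing)
        aln = CodonAlignment({"a": row, "b": "A" * 100}, [])
        survivors = step3_missingness_filter(aln, 0.25)
        assert ("a" in survivors) is kept

    def test_gaps_count_as_missing(self):
        aln = CodonAlignment({"a": "-" * 30 + "A" * 70, "b": "A" * 100}, [])
        assert step3_missingness_filter(aln, 0.25) == ["b"]


class TestOccupancy:
    @pytest.mark.parametrize(
        "min_samples, total, pct", [(30, 41, 73), (20, 30, 67), (20, 41, 49)]
    )
    def test_occupancy_label(self, min_samples, total, pct):
        assert occupancy_percent(min_samples, total) == pct

    def test_small_cluster_dropped(self):
        alns = {
            "big": CodonAlignment({f"s{i}": "AAA" for i in range(20)}, []),
            "small": CodonAlignment({f"s{i}": "AAA" for i in range(19)}, []),
        }
        retained, occ = occupancy_filter(alns, 20, total_samples=30)
        assert set(retained) == {"big"}
        assert occ == 67

    def test_min_samples_above_total_is_config_error(self):
        with pytest.raises(ValueError):
            occupancy_filter({}, 10, total_samples=5)


class TestDistanceStats:
    def test_hand_arithmetic(self):
        def aln_with_max(d):
            n = 100
            far = "C" * d + "A" * (n - d)
            return CodonAlignment({"a": "A" * n, "b": far}, [])

        stats = distance_threshold_stats(
            {"c1": aln_with_max(10), "c2": aln_with_max(20), "c3": aln_with_max(30)}
        )
        assert stats.mean == pytest.approx(20.0)
        assert stats.median == pytest.approx(20.0)
        assert stats.sd == pytest.approx(10.0)  # sample SD

    def test_single_cluster_sd_zero(self):
        stats = distance_threshold_stats(
            {"c1": CodonAlignment({"a": "AAAA", "b": "AATT"}, [])}
        )
        assert stats.mean == stats.median == 50.0
        assert stats.sd == 0.0

    def test_matches_recomputation(self, clean_dataset):
        from orthosweep.codon_align import align_cluster

        alns = {
            cid: align_cluster({r.sample_id: r.sequence for r in cl})
            for cid, cl in clean_dataset.clusters.items()
        }
        stats = distance_threshold_stats(alns)
        maxima = []
        for cid, aln in alns.items():
            dm = pdistance_matrix(aln)
            vals = dm.values[np.triu_indices(len(dm.ids), k=1)]
            maxima.append(np.nanmax(vals))
        assert stats.mean == pytest.approx(np.mean(maxima))
        assert stats.median == pytest.approx(np.median(maxima))
        assert stats.sd == pytest.approx(np.std(maxima, ddof=1))


class TestPipeline:
    def test_bookkeeping_formula(self):
        s = summarize_alignments(2591, 2_931_129)
        assert s.mean_length == pytest.approx(1131.27, abs=0.005)

    def test_clean_run_keeps_everything(self, clean_dataset):
        params = FilterParams(
            len_var_pct=100.0, max_mean_dist=90.0, max_missing_frac=0.9, min_samples=2
        )
        alns, report, summary = run_pipeline(clean_dataset.clusters, params)
        n_in = sum(len(c) for c in clean_dataset.clusters.values())
        assert summary.clusters == len(clean_dataset.clusters)
        df = report.to_dataframe()
        assert (df.step == "retained").sum() == n_in

    def test_report_partitions_records(self, contaminated_dataset):
        alns, report, summary = run_pipeline(
            contaminated_dataset.clusters, FilterParams(min_samples=2)
        )
        df = report.to_dataframe()
        n_in = sum(len(c) for c in contaminated_dataset.clusters.values())
        assert len(df) == n_in
        assert not df.duplicated(["cluster_id", "sample_id"]).any()

    def test_per_step_monotonicity(self, contaminated_dataset):
        """Relaxing a step's own threshold can only grow its survivor set."""
        cid, cluster = next(iter(contaminated_dataset.clusters.items()))
        tight = {r.sample_id for r in step1_length_filter(cluster, 10.0)}
        loose = {r.sample_id for r in step1_length_filter(cluster, 50.0)}
        assert tight <= loose

        from orthosweep.codon_align import align_cluster

        survivors = step1_length_filter(cluster, 50.0)
        aln = align_cluster({r.sample_id: r.sequence for r in survivors})
        s2_tight = set(step2_distance_filter(aln, 10.0))
        s2_loose = set(step2_distance_filter(aln, 40.0))
        assert s2_tight <= s2_loose
        s3_tight = set(step3_missingness_filter(aln, 0.05))
        s3_loose = set(step3_missingness_filter(aln, 0.5))
        assert s3_tight <= s3_loose

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            run_pipeline([])
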