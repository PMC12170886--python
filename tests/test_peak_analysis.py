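import numpy as np
import pandas as pd
import pytest

from tsppi import peak_analysis as pa
from tsppi.genomic_core import (
    CoverageTrack,
    FeatureTrack,
    GeneModel,
    GenomicInterval,
)

IV = GenomicInterval


def random_peak_sets(rng, n_samples=4, n_peaks=50, span=20_000):
    sets = {}
    for s in range(n_samples):
        ivs = []
        for _ in range(n_peaks):
            chrom = f"chr{rng.integers(1, 3)}"
            start = int(rng.integers(0, span))
            ivs.append(IV(chrom, start, start + int(rng.integers(50, 400))))
        sets[f"s{s}"] = ivs
    return sets


def simple_matrix(values, columns, index=None):
    df = pd.DataFrame(values, columns=columns, index=index)
    peaks = [pa.ConsensusPeak(str(i), IV("chr1", 10 * k, 10 * k + 5)) for k, i in enumerate(df.index)]
    for p, i in zip(peaks, df.index):
        p.peak_id = str(i)
    df.index = [str(i) for i in df.index]
    return pa.PeakMatrix(peaks, df, read_length=100)


class TestConsensus:
    def test_identical_peaks_merge_to_one(self):
        sets = {f"s{i}": [IV("chr1", 100, 300)] for i in range(6)}
        catalog = pa.build_consensus(sets)
        assert len(catalog) == 1 and catalog[0].n_samples == 6

    def test_distant_peaks_stay_separate(self):
        catalog = pa.build_consensus({"s": [IV("chr1", 0, 100), IV("chr1", 500, 600)]})
        assert len(catalog) == 2

    def test_chain_merges_transitively(self):
        # midpoints 49, 99, 149: s2 matches s1 (99 in [0,100)) and s3
        # matches s2 (149 in [50,150)), but s1 and s3 never match directly
        sets = {"s1": [IV("chr1", 0, 100)], "s2": [IV("chr1", 50, 150)], "s3": [IV("chr1", 100, 200)]}
        catalog = pa.build_consensus(sets)
        assert len(catalog) == 1
        assert (catalog[0].interval.start, catalog[0].interval.end) == (0, 200)

    def test_overlap_without_midpoint_containment_does_not_match(self):
        # [0,100) and [90,300): midpoints 49 and 194; neither inside the other
        catalog = pa.build_consensus({"s": [IV("chr1", 0, 100), IV("chr1", 90, 300)]})
        assert len(catalog) == 2

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_sweep_equals_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sets = random_peak_sets(rng)
        fast = pa.build_consensus(sets)
        slow = pa.build_consensus_bruteforce(sets)
        assert [(p.interval.chrom, p.interval.start, p.interval.end) for p in fast] == [
            (p.interval.chrom, p.interval.start, p.interval.end) for p in slow
        ]

    def test_invariant_to_sample_and_peak_order(self):
        rng = np.random.default_rng(9)
        sets = random_peak_sets(rng, n_samples=3, n_peaks=30)
        base = pa.build_consensus(sets)
        reordered = {k: list(reversed(v)) for k, v in reversed(list(sets.items()))}
        again = pa.build_consensus(reordered)
        assert [(p.interval.start, p.interval.end) for p in base] == [
            (p.interval.start, p.interval.end) for p in again
        ]

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError):
            pa.build_consensus({"s": [IV("chrX", 0, 10)]}, known_chroms=["chr1"])


class TestQuantify:
    def test_uniform_coverage_amplitude(self):
        catalog = [pa.ConsensusPeak("p0", IV("chr1", 100, 300))]
        track = CoverageTrack.from_records([("chr1", 0, 1000, 10.0)])
        m = pa.quantify(catalog, {"s1": track}, read_length=100)
        assert m.values.loc["p0", "s1"] == pytest.approx(20.0)  # 200 bp * 10 / 100

    def test_doubling_read_length_halves_amplitude(self):
        catalog = [pa.ConsensusPeak("p0", IV("chr1", 0, 100))]
        track = CoverageTrack.from_records([("chr1", 0, 100, 4.0)])
        m1 = pa.quantify(catalog, {"s": track}, 50)
        m2 = pa.quantify(catalog, {"s": track}, 100)
        assert m1.values.loc["p0", "s"] == 2 * m2.values.loc["p0", "s"]

    def test_missing_chromosome_gives_zero(self):
        catalog = [pa.ConsensusPeak("p0", IV("chr9", 0, 100))]
        track = CoverageTrack.from_records([("chr1", 0, 100, 4.0)])
        m = pa.quantify(catalog, {"s": track}, 100)
        assert m.values.loc["p0", "s"] == 0.0


class TestNoiseThreshold:
    def test_floor_and_drop_semantics(self):
        m = simple_matrix([[5.0, 5.0], [15.0, 40.0], [30.0, 50.0]], ["a", "b"])
        out = pa.apply_noise_threshold(m, 20.0)
        assert list(out.values.index) == ["1", "2"]  # all-floored row dropped
        assert out.values.loc["1"].tolist() == [20.0, 40.0]
        assert len(out.peaks) == 2

    def test_tiny_threshold_is_identity_on_positive_matrix(self):
        m = simple_matrix([[5.0, 7.0], [9.0, 11.0]], ["a", "b"])
        out = pa.apply_noise_threshold(m, 1e-9)
        assert np.allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            pa.apply_noise_threshold(simple_matrix([[1.0]], ["a"]), 0.0)


class TestModeScaling:
    def test_constant_multiple_recovered(self):
        rng = np.random.default_rng(0)
        control = rng.lognormal(np.log(100), 0.3, 500)
        m = simple_matrix(
            np.column_stack([control, control * 4.0]), ["control", "kd"],
        )
        out = pa.scale_to_control_mode(m, {"kd": "control", "control": "control"})
        ratio = out.values["kd"] / out.values["control"]
        assert np.median(ratio) == pytest.approx(1.0, abs=0.15)

    def test_modes_align_within_one_bin(self):
        rng = np.random.default_rng(1)
        cols = {
            "control": rng.lognormal(np.log(80), 0.4, 800),
            "kd1": 2.7 * rng.lognormal(np.log(80), 0.4, 800),
            "kd2": 0.4 * rng.lognormal(np.log(80), 0.4, 800),
        }
        m = simple_matrix(np.column_stack(list(cols.values())), list(cols))
        out = pa.scale_to_control_mode(m, {c: "control" for c in cols})
        modes = {c: pa._log2_mode(out.values[c].to_numpy()) for c in cols}
        for c in cols:
            assert abs(modes[c] - modes["control"]) <= 0.1 + 1e-9

    def test_identity_for_sample_equal_to_control(self):
        vals = np.array([[10.0, 10.0], [20.0, 20.0], [40.0, 40.0]])
        m = simple_matrix(vals, ["control", "kd"])
        out = pa.scale_to_control_mode(m, {"kd": "control", "control": "control"})
        assert np.allclose(out.values["kd"], vals[:, 1])


class TestQuantileNormalisation:
    def test_identical_columns_unchanged(self):
        vals = np.array([[1.0, 1.0], [5.0, 5.0], [9.0, 9.0]])
        m = simple_matrix(vals, ["a", "b"])
        out = pa.quantile_normalise(m)
        assert np.allclose(out.values.to_numpy(), vals)

    def test_columns_become_identical_multisets(self):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(3, 1, size=(50, 4))
        m = simple_matrix(vals, list("abcd"))
        out = pa.quantile_normalise(m)
        ref = np.sort(out.values["a"].to_numpy())
        for c in "bcd":
            assert np.allclose(np.sort(out.values[c].to_numpy()), ref)

    def test_2x2_order_statistic_means(self):
        m = simple_matrix([[1.0, 10.0], [3.0, 20.0]], ["a", "b"])
        out = pa.quantile_normalise(m)
        # sorted-column means: [(1+10)/2, (3+20)/2] = [5.5, 11.5]
        assert out.values["a"].tolist() == [5.5, 11.5]
        assert out.values["b"].tolist() == [5.5, 11.5]

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            pa.quantile_normalise(simple_matrix([[1.0]], ["a"]))


class TestDisappearing:
    def test_threshold_boundary_inclusive(self):
        m = simple_matrix(
            [[40.0, 20.0], [30.0, 30.0], [20.0 * 2**0.5, 20.0]], ["control", "kd"]
        )
        ids, fc = pa.call_disappearing(m, "control", "kd", 0.5)
        assert ids == {"0", "2"}
        assert fc.loc["0"] == pytest.approx(1.0)
        assert fc.loc["2"] == pytest.approx(0.5)

    def test_classification_definitions(self):
        catalog = ["p1", "p2", "p3", "p4"]
        disappearing = {
            ("A", "A"): {"p1", "p3"},
            ("B", "A"): {"p3"},
            ("A", "B"): {"p3"},
            ("B", "B"): {"p2", "p3"},
        }
        res = pa.classify_codependency(disappearing, catalog)
        assert res.classes == {
            "p1": "A_specific",
            "p2": "B_specific",
            "p3": "shared",
            "p4": "unchanged",
        }

    def test_empty_sets_give_all_unchanged(self):
        disappearing = {(ip, kd): set() for ip in "AB" for kd in "AB"}
        res = pa.classify_codependency(disappearing, ["p1"])
        assert res.classes == {"p1": "unchanged"}

    def test_reduced_in_both_ips_under_one_kd_is_specific(self):
        disappearing = {
            ("A", "A"): {"p1"},
            ("B", "A"): {"p1"},
            ("A", "B"): set(),
            ("B", "B"): set(),
        }
        res = pa.classify_codependency(disappearing, ["p1"])
        assert res.classes["p1"] == "A_specific"


class TestTruthRecovery:
    def test_noise_free_classification_recovers_planted_classes_exactly(self, noise_free_peaks):
        d = noise_free_peaks
        catalog = pa.build_consensus(d["chip_peaks"], known_chroms=d["genome"].chroms)
        matrix = pa.quantify(catalog, d["chip_cov"], d["config"].read_length)
        matrix = pa.apply_noise_threshold(matrix, 20.0)
        control_of = {s: f"chip_{s.split('_')[1]}_control" for s in matrix.values.columns}
        matrix = pa.scale_to_control_mode(matrix, control_of)
        plan = {
            (ip, cond): f"chip_ip{ip}_{'control' if cond == 'control' else 'kd' + cond}"
            for ip in "AB"
            for cond in ("control", "A", "B")
        }
        result = pa.run_codependency(matrix, plan)
        # map each consensus peak to its planted locus via the member name
        truth = d["truth"]
        recovered = {}
        for peak in catalog:
            names = {iv.name for ivs in peak.members.values() for iv in ivs}
            assert len(names) == 1  # no spurious merges of distinct loci
            recovered[names.pop()] = result.classes[peak.peak_id]
        assert recovered == truth.peak_classes

    def test_default_noise_class_recall_at_least_095(self, default_run):
        config, report, outdir = default_run
        classes = pd.read_csv(outdir / "peak_classes.tsv", sep="\t")
        consensus = pd.read_csv(
            outdir / "consensus_peaks.bed",
            sep="\t",
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
        import json

        truth = json.loads((outdir / "sim" / "sim_truth.json").read_text())
        by_pos = {
            (chrom, s, e): cls
            for (locus, cls), (chrom, s, e) in zip(
                truth["peak_classes"].items(), truth["peak_intervals"].values()
            )
        }
        merged = consensus.merge(classes, left_on="name", right_on="peak_id")
        per_class_hits: dict[str, list[int]] = {}
        for _, row in merged.iterrows():
            centre = (row["start"] + row["end"]) // 2
            match = [
                cls
                for (chrom, s, e), cls in by_pos.items()
                if chrom == row["chrom"] and s <= centre < e
            ]
            assert len(match) == 1
            true_cls = match[0]
            per_class_hits.setdefault(true_cls, []).append(int(row["class"] == true_cls))
        for cls, hits in per_class_hits.items():
            assert np.mean(hits) >= 0.95, f"recall for {cls} below 0.95"


class TestAnnotation:
    def make_gene(self):
        return GeneModel(
            "g1", "G1", IV("chr1", 10_000, 12_000, "+"),
            exons=(IV("chr1", 10_000, 10_600, "+"), IV("chr1", 11_200, 12_000, "+")),
        )

    def test_peak_inside_exon(self):
        catalog = [pa.ConsensusPeak("p0", IV("chr1", 10_100, 10_300))]
        ann = pa.annotate(catalog, [self.make_gene()], [])
        assert "exon" in ann.iloc[0]["labels"]

    def test_boundary_half_overlap_is_inclusive(self):
        # promoter is [8000, 10000); peak [9900, 10100) is covered exactly 50%
        catalog = [pa.ConsensusPeak("p0", IV("chr1", 9_900, 10_100))]
        ann = pa.annotate(catalog, [self.make_gene()], [])
        assert "promoter" in ann.iloc[0]["labels"]

    def test_forty_percent_overlap_not_labelled(self):
        track = FeatureTrack("cpg_island", [IV("chr1", 0, 40)])
        catalog = [pa.ConsensusPeak("p0", IV("chr1", 0, 100))]
        ann = pa.annotate(catalog, [], [track])
        assert ann.iloc[0]["labels"] == ""


class TestGenePairing:
    genes = [GeneModel("g1", "G1", IV("chr1", 2_000, 3_000, "+"))]

    def test_gene_within_flank_paired_with_gap_distance(self):
        catalog = [pa.ConsensusPeak("p0", IV("chr1", 1_000, 1_700))]
        pairs = pa.pair_with_genes(catalog, self.genes, flank_bp=1000)
        assert len(pairs) == 1 and pairs.iloc[0]["distance_bp"] == 300

    def test_gene_beyond_flank_not_paired(self):
        catalog = [pa.ConsensusPeak("p0", IV("chr1", 1_000, 1_700))]
        pairs = pa.pair_with_genes(catalog, [GeneModel("g2", "G2", IV("chr1", 8_000, 9_000, "+"))], 5000)
        assert len(pairs) == 0

    def test_zero_flank_requires_overlap(self):
        catalog = [pa.ConsensusPeak("p0", IV("chr1", 2_500, 2_600))]
        pairs = pa.pair_with_genes(catalog, self.genes, flank_bp=0)
        assert len(pairs) == 1 and pairs.iloc[0]["distance_bp"] == 0


class TestProfiles:
    def test_uniform_coverage_flat_profile(self):
        track = CoverageTrack.from_records([("chr1", 0, 10_000, 2.0)])
        mats = pa.tss_profile_matrix({"s": track}, [("chr1", 5_000)], 2000, 100)
        assert np.allclose(mats["s"], 2.0)

    def test_control_sums_equalised_and_factor_shared_with_kd(self):
        t1 = CoverageTrack.from_records([("chr1", 0, 10_000, 1.0)])
        t2 = CoverageTrack.from_records([("chr1", 0, 10_000, 2.0)])
        kd = CoverageTrack.from_records([("chr1", 0, 10_000, 2.0)])
        mats = pa.tss_profile_matrix(
            {"c1": t1, "c2": t2, "kd2": kd},
            [("chr1", 5_000)],
            2000,
            100,
            control_of={"c1": "c1", "c2": "c2", "kd2": "c2"},
        )
        assert mats["c1"].sum() == pytest.approx(mats["c2"].sum())
        # kd2 shares c2's factor (0.5), so it matches c1's uniform level
        assert np.allclose(mats["kd2"], mats["c1"])

    def test_profile_peaks_at_centre_for_planted_peak(self, noise_free_peaks):
        d = noise_free_peaks
        truth = d["truth"]
        locus = next(iter(truth.peak_intervals))
        chrom, s, e = truth.peak_intervals[locus]
        centre = (s + e) // 2
        track = d["chip_cov"]["chip_ipA_control"]
        mats = pa.tss_profile_matrix({"s": track}, [(chrom, centre)], 2000, 100)
        profile = mats["s"][0]
        assert abs(int(np.argmax(profile)) - 50) <= 1

    def test_edge_anchor_padded_with_zeros(self):
        track = CoverageTrack.from_records([("chr1", 0, 1_000, 1.0)])
        mats = pa.tss_profile_matrix({"s": track}, [("chr1", 100)], 2000, 100)
        assert mats["s"][0][0] == 0.0  # bins before the chromosome start


class TestAccessibility:
    def test_control_vs_itself_is_zero(self):
        m = simple_matrix([[30.0, 30.0], [50.0, 50.0]], ["control", "control2"])
        fc = pa.accessibility_change(m, "control", "control2")
        assert np.allclose(fc["log2fc"], 0.0)

    def test_planted_atac_reduction_recovered(self, noise_free_peaks):
        d = noise_free_peaks
        truth = d["truth"]
        regions = [
            pa.ConsensusPeak(sid, IV(chrom, s, e))
            for sid, chrom, s, e in truth.atac_regions
        ]
        matrix = pa.quantify(regions, d["atac_cov"], d["config"].read_length)
        reduced = {sid for sid, flag in truth.atac_sites.items() if flag}
        raw_b = pa.accessibility_change(matrix, "atac_control", "atac_kdB")
        raw_at_reduced = raw_b[raw_b["peak_id"].isin(reduced)]["log2fc"]
        assert raw_at_reduced.mean() == pytest.approx(1.0, abs=0.01)
        qn = pa.quantile_normalise(matrix)
        fc_b = pa.accessibility_change(qn, "atac_control", "atac_kdB")
        fc_a = pa.accessibility_change(qn, "atac_control", "atac_kdA")
        at_reduced_b = fc_b[fc_b["peak_id"].isin(reduced)]["log2fc"]
        at_reduced_a = fc_a[fc_a["peak_id"].isin(reduced)]["log2fc"]
        # quantile normalisation compresses but preserves the B-KD-only signal
        assert at_reduced_b.mean() > 0.5
        assert abs(at_reduced_a.mean()) < 0.1
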