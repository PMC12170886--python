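import hashlib
from dataclasses import replace

import numpy as np
import pytest

from tsppi import synthetic_data as sd
from tsppi.genomic_core import read_bed, read_bedgraph, read_fasta


def small_config(seed=0):
    return sd.SimConfig(
        seed=seed,
        n_chroms=1,
        chrom_len=300_000,
        n_genes=30,
        peaks=sd.PeakPlan(
            n_a_specific=10, n_b_specific=5, n_shared=12, n_unchanged=20,
            n_linked_down=3, n_linked_up=4,
        ),
        de=sd.DePlan(
            n_co_up=10, n_co_down=8, n_discordant=1,
            n_a_only_up=5, n_a_only_down=4, n_b_only_up=6, n_b_only_down=3,
            n_null=50,
        ),
    )


def tree_hashes(root):
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(root.iterdir())
        if p.is_file()
    }


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        config = small_config(seed=42)
        sd.simulate_all(config, tmp_path / "run1")
        sd.simulate_all(config, tmp_path / "run2")
        assert tree_hashes(tmp_path / "run1") == tree_hashes(tmp_path / "run2")

    def test_different_seed_changes_outputs(self, tmp_path):
        sd.simulate_all(small_config(seed=1), tmp_path / "a")
        sd.simulate_all(small_config(seed=2), tmp_path / "b")
        h1, h2 = tree_hashes(tmp_path / "a"), tree_hashes(tmp_path / "b")
        assert h1["genome.fa"] != h2["genome.fa"]


class TestGenome:
    def test_gc_fraction_within_band(self):
        config = replace(small_config(), gc_background=0.5)
        rng = np.random.default_rng(0)
        genome, _, _ = sd.simulate_genome(config, rng)
        seq = genome.sequences["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.48 <= gc <= 0.52

    def test_zero_genes_valid_genome(self):
        config = replace(small_config(), n_genes=0)
        rng = np.random.default_rng(0)
        genome, genes, _ = sd.simulate_genome(config, rng)
        assert genes == [] and len(genome.sequences["chr1"]) == config.chrom_len

    def test_genome_too_small_rejected(self):
        config = replace(small_config(), chrom_len=10_000, n_genes=500)
        with pytest.raises(ValueError):
            sd.simulate_genome(config, np.random.default_rng(0))

    def test_gene_models_pass_validators(self):
        config = small_config()
        genome, genes, tracks = sd.simulate_genome(config, np.random.default_rng(1))
        for g in genes:
            assert g.interval.end <= genome.length(g.interval.chrom)
            assert g.tss == (g.interval.start if g.strand == "+" else g.interval.end - 1)


class TestPeakExperiment:
    def test_generated_files_pass_format_validators(self, tmp_path):
        sd.simulate_all(small_config(), tmp_path)
        genome = read_fasta(tmp_path / "genome.fa")
        assert set(genome.chroms) == {"chr1"}
        for ip, cond in sd.CHIP_SAMPLES:
            ivs = read_bed(tmp_path / f"chip_{ip}_{cond}.bed")
            assert len(ivs) > 0
            track = read_bedgraph(tmp_path / f"chip_{ip}_{cond}.bedgraph")
            assert track.total_mass() > 0

    def test_reduction_halves_amplitude_log2fc_one(self, noise_free_peaks):
        """Shared loci lose half their coverage under either knockdown, in both IPs."""
        d = noise_free_peaks
        truth, cov = d["truth"], d["chip_cov"]
        rl = d["config"].read_length
        shared = [lid for lid, cls in truth.peak_classes.items() if cls == "shared"][:20]
        for lid in shared:
            chrom, s, e = truth.peak_intervals[lid]
            for ip in ("ipA", "ipB"):
                ctrl = cov[f"chip_{ip}_control"].sum_over(chrom, s, e) / rl
                for kd in ("kdA", "kdB"):
                    kdv = cov[f"chip_{ip}_{kd}"].sum_over(chrom, s, e) / rl
                    assert np.log2(ctrl / kdv) == pytest.approx(1.0, abs=0.02)

    def test_specific_locus_untouched_by_other_knockdown(self, noise_free_peaks):
        d = noise_free_peaks
        truth, cov = d["truth"], d["chip_cov"]
        a_spec = [lid for lid, cls in truth.peak_classes.items() if cls == "A_specific"][:20]
        for lid in a_spec:
            chrom, s, e = truth.peak_intervals[lid]
            ctrl = cov["chip_ipA_control"].sum_over(chrom, s, e)
            other = cov["chip_ipA_kdB"].sum_over(chrom, s, e)
            assert np.log2(ctrl / other) == pytest.approx(0.0, abs=1e-6)

    def test_full_planting_rate_places_motif_in_every_shared_locus(self):
        config = small_config()
        config = replace(config, motif=sd.MotifPlan(kmer="GCCGCC", planting_rate=1.0))
        rng = np.random.default_rng(0)
        genome, genes, _ = sd.simulate_genome(config, rng)
        _, _, _, truth = sd.simulate_peak_experiment(config, genome, genes, rng)
        for lid, cls in truth.peak_classes.items():
            if cls == "shared":
                chrom, s, e = truth.peak_intervals[lid]
                assert "GCCGCC" in genome.sequences[chrom][s:e]


class TestDeTables:
    def test_all_zero_plan_gives_empty_shared(self):
        config = small_config()
        config = replace(
            config,
            de=sd.DePlan(
                n_co_up=0, n_co_down=0, n_discordant=0,
                n_a_only_up=0, n_a_only_down=0, n_b_only_up=0, n_b_only_down=0,
                n_null=10,
            ),
        )
        de_a, de_b, truth = sd.simulate_de_tables(config, np.random.default_rng(0))
        assert (de_a["p_adj"] >= 0.05).all() and (de_b["p_adj"] >= 0.05).all()

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError):
            sd.DePlan(correlation=1.0)

    def test_linked_gene_ids_used_for_first_shared_genes(self):
        config = small_config()
        de_a, de_b, truth = sd.simulate_de_tables(
            config, np.random.default_rng(0), ["gX", "gY"], ["gZ"]
        )
        assert truth.de_classes["gX"] == "co_down"
        assert truth.de_classes["gZ"] == "co_up"
        assert set(de_a["gene_id"]) >= {"gX", "gY", "gZ"}


class TestInteractomeGenerator:
    def test_candidate_in_all_a_runs_and_nowhere_else(self):
        config = small_config()
        runs_a, runs_b, truth = sd.simulate_interactome_runs(config, np.random.default_rng(7))
        cand = truth.candidate_accession
        for run in runs_a:
            baits = {h.accession for h in run.bait_hits}
            iggs = {h.accession for h in run.igg_hits}
            assert cand in baits and cand not in iggs
        for run in runs_b:
            assert cand not in {h.accession for h in run.bait_hits}

    def test_zero_contaminants_makes_subtraction_noop(self):
        from tsppi.interactome import filter_run

        config = small_config()
        config = replace(config, interactome=replace(config.interactome, n_contaminants=0))
        runs_a, _, _ = sd.simulate_interactome_runs(config, np.random.default_rng(7))
        run = runs_a[0]
        assert filter_run(run) == {h.accession for h in run.bait_hits}


class TestSensorgramGenerator:
    def test_truth_kd_is_kd_over_ka(self):
        config = small_config()
        _, truth = sd.simulate_sensorgrams(config, np.random.default_rng(0))
        assert truth.true_kd_nM == pytest.approx(870.0)

    def test_noise_free_blank_is_zero_after_referencing(self):
        from tsppi.binding_kinetics import double_reference

        config = small_config().noise_free()
        pairs, _ = sd.simulate_sensorgrams(config, np.random.default_rng(0))
        blank_a, blank_r = pairs[0]
        out = double_reference(blank_a, blank_r, blank_a, blank_r)
        assert np.allclose(out.response_RU, 0.0, atol=1e-9)

    def test_csv_round_trip(self, tmp_path):
        config = small_config()
        pairs, _ = sd.simulate_sensorgrams(config, np.random.default_rng(0))
        path = tmp_path / "sg.csv"
        sd.write_sensorgram_csv(pairs, path)
        back = sd.read_sensorgram_csv(path)
        assert len(back) == len(pairs)
        concs = sorted(a.concentration_nM for a, _ in back)
        assert concs == sorted(a.concentration_nM for a, _ in pairs)

    def test_invalid_kinetic_parameters_rejected(self):
        config = small_config()
        config = replace(config, spr=replace(config.spr, ka_per_M_s=-1.0))
        with pytest.raises(ValueError):
            sd.simulate_sensorgrams(config, np.random.default_rng(0))
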