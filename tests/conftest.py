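import numpy as np
import pytest

from tsppi import pipeline as pl
from tsppi import synthetic_data as sd


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default synthetic dataset (default noise)."""
    outdir = tmp_path_factory.mktemp("pipeline_run")
    config = pl.PipelineConfig(seed=11, outdir=str(outdir))
    report = pl.run_all(config)
    return config, report, outdir


@pytest.fixture(scope="session")
def noise_free_peaks():
    """Noise-free peak experiment with its planted truth (in memory)."""
    config = sd.SimConfig(seed=7).noise_free()
    rng = np.random.default_rng(config.seed)
    genome, genes, tracks = sd.simulate_genome(config, rng)
    chip_peaks, chip_cov, atac_cov, truth = sd.simulate_peak_experiment(config, genome, genes, rng)
    return {
        "config": config,
        "genome": genome,
        "genes": genes,
        "tracks": tracks,
        "chip_peaks": chip_peaks,
        "chip_cov": chip_cov,
        "atac_cov": atac_cov,
        "truth": truth,
    }
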