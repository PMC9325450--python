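import numpy as np
import pandas as pd
import pytest

from lotus_popgen.containers import GenotypeMatrix, site_table
from lotus_popgen.sim import STANDARD_WINDOW, simulate_dataset, standard_sweep_config


def toy_matrix(dosage, chrom="chr1", start_pos=100, spacing=100, samples=None):
    """Build a GenotypeMatrix from a literal dosage array (-1 = missing)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_samples, n_sites = dosage.shape
    if samples is None:
        samples = [f"s{i + 1}" for i in range(n_samples)]
    pos = start_pos + spacing * np.arange(n_sites)
    called = dosage != -1
    n_called = called.sum(axis=0)
    alt_af = np.where(called, dosage, 0).sum(axis=0) / np.maximum(2 * n_called, 1)
    sites = site_table(
        chrom=[chrom] * n_sites,
        pos=pos,
        ref=["A"] * n_sites,
        alt=["T"] * n_sites,
        depth=np.full(n_sites, 10.0),
        rms_mq=np.full(n_sites, 40.0),
        call_fraction=n_called / n_samples,
        maf=np.minimum(alt_af, 1 - alt_af),
    )
    return GenotypeMatrix(samples=list(samples), sites=sites, dosage=dosage)


@pytest.fixture(scope="session")
def standard_dataset():
    """The standard 2 Mb / 20 000-SNP two-population sweep benchmark, seed 1."""
    cfg = standard_sweep_config(1)
    geno, truth, genes = simulate_dataset(cfg)
    return cfg, geno, truth, genes


@pytest.fixture(scope="session")
def standard_window_spec():
    from lotus_popgen.stats import WindowSpec

    return WindowSpec(*STANDARD_WINDOW)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_901)
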