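import warnings

import pytest

from plastcomp.synthetic import SyntheticConfig, generate_reference, mutate_genome


@pytest.fixture(autouse=True)
def _quiet_trim_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def small_pair():
    """A compact synthetic genome pair with ground truth (session-cached)."""
    cfg = SyntheticConfig(genome_length=30_000, n_genes=14, n_snv=60,
                          frac_nonsyn=0.3, n_indels=8, seed=42)
    ref, truth0 = generate_reference(cfg)
    qry, truth = mutate_genome(ref, truth0, cfg)
    return cfg, ref, qry, truth


@pytest.fixture(scope="session")
def inverted_pair():
    """Like small_pair but the derived genome carries a block inversion."""
    cfg = SyntheticConfig(genome_length=30_000, n_genes=14, n_snv=60,
                          frac_nonsyn=0.3, n_indels=8, invert_block="auto", seed=43)
    ref, truth0 = generate_reference(cfg)
    qry, truth = mutate_genome(ref, truth0, cfg)
    return cfg, ref, qry, truth
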