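import pytest

from crosstf.synthgen import SynthConfig, generate


SMALL = dict(
    source_chroms=(("mchr1", 1_000_000), ("mchr2", 1_000_000)),
    target_chroms=(("hchr1", 1_000_000), ("hchr2", 1_000_000)),
    n_blocks=12,
    peaks_per_factor=100,
    dst_only_peaks_per_factor=50,
    esc_only_peaks_per_factor=10,
    n_genes=200,
)


def small_config(seed: int = 0, **overrides) -> SynthConfig:
    return SynthConfig(seed=seed, **{**SMALL, **overrides})


@pytest.fixture(scope="session")
def small_dataset():
    """A fast two-chromosome dataset with all stages planted."""
    return generate(small_config(seed=101))


@pytest.fixture(scope="session")
def default_dataset():
    """The full default study conditions (4 factors x 1000 peaks, 40%
    syntenic genome)."""
    return generate(SynthConfig(seed=7))
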