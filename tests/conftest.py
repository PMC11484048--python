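"""Shared fixtures: small diverged genome pairs with known truth.

Everything is generated programmatically at session scope so the expensive
pairs are built once per run.
"""

import pytest

from crossmeth import synthgen as sg


@pytest.fixture(scope="session")
def small_pair():
    """~120-kb single-chromosome pair with SNPs and a few SVs."""
    cfg = sg.SynthConfig(n_chrom=1, chrom_len=120_000, sv_count=4, seed=3)
    genome_a = sg.generate_genome(cfg)
    genome_b, truth, cmap = sg.diverge_genome(genome_a, cfg)
    return cfg, genome_a, genome_b, truth, cmap


@pytest.fixture(scope="session")
def snp_only_pair():
    """200-kb pair with substitutions only (no SVs): clean colinear truth."""
    cfg = sg.SynthConfig(n_chrom=1, chrom_len=200_000, sv_count=0, seed=9)
    genome_a = sg.generate_genome(cfg)
    genome_b, truth, cmap = sg.diverge_genome(genome_a, cfg)
    return cfg, genome_a, genome_b, truth, cmap
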