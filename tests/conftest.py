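"""Shared fixtures: a seeded reference panel and planted-genome worlds.

Everything is generated programmatically by the synthdata module; the
expensive assembled fixtures are session-scoped so the reconstruction,
operon and determinism tests share one computation.
"""

from __future__ import annotations

import dataclasses

import pytest

from genetarget import assemble, synthdata as sd


@pytest.fixture(scope="session")
def default_config() -> sd.SynthConfig:
    return sd.SynthConfig(seed=11)


@pytest.fixture(scope="session")
def panel(default_config):
    return sd.make_reference_panel(default_config)


def make_world(seed: int, **overrides):
    """One planted-operon world: panel, genomes, reads, truth."""
    cfg = sd.SynthConfig(seed=seed, **overrides)
    panel = sd.make_reference_panel(cfg)
    genomes, truth = sd.plant_genomes(panel, cfg)
    design = sd.ring_design(cfg)
    reads, design, truth = sd.simulate_samples(genomes, truth, cfg,
                                               design=design)
    return cfg, panel, genomes, reads, truth


# conditions of the error-free reconstruction arm: paired 2x150 reads from
# 290 bp fragments, overlap-merged, 10x coverage, one genome per fixture
CLEAN_ARM = dict(n_genomes=1, paired=True, error_rate=0.0,
                 background_fraction=0.0, coverage_per_sample=10.0,
                 ring_radii=(1.0,), samples_per_ring=0)

# conditions of the error arm: single-end 150 bp reads at 20x with 0.5%
# substitution errors (short reads keep every error path a clippable tip
# at the largest k)
ERROR_ARM = dict(n_genomes=1, paired=False, error_rate=0.005,
                 background_fraction=0.0, coverage_per_sample=20.0,
                 ring_radii=(1.0,), samples_per_ring=0)

CLEAN_SEEDS = list(range(300, 320))
ERROR_SEEDS = list(range(400, 420))


def assemble_world(world):
    cfg, panel, genomes, reads, truth = world
    if cfg.paired:
        reads = assemble.merge_readset(reads)
    contigs = assemble.assemble_multi_k(reads, assemble.AssemblyConfig())
    return contigs


@pytest.fixture(scope="session")
def error_arm_fixtures():
    """20 assembled error-arm worlds, shared by reconstruction-with-error
    and operon-recovery tests."""
    out = []
    for seed in ERROR_SEEDS:
        world = make_world(seed, **ERROR_ARM)
        out.append((world, assemble_world(world)))
    return out
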