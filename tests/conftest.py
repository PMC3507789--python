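"""Shared fixtures: small synthetic worlds materialized on disk.

Everything is generated programmatically at test time; expensive pipeline
runs are session-scoped so several tests can share one annotation.
"""

from __future__ import annotations


import pytest

from synann import io as sio
from synann.fixtures import (
    FixtureSpec,
    build_reference_world,
    derive_target_genome,
    inject_frameshifts_and_reads,
)
from synann.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def small_world():
    spec = FixtureSpec(seed=101, n_pillars=30, divergence=0.1,
                       intron_fraction=0.1, tandem_count=2, paralog_pairs=2)
    world = build_reference_world(spec)
    target = derive_target_genome(world)
    return spec, world, target


@pytest.fixture(scope="session")
def small_run(small_world, tmp_path_factory):
    """One shared pipeline run over the small fixture."""
    spec, world, target = small_world
    d = tmp_path_factory.mktemp("small_run")
    scaffolds = str(d / "scaffolds.fasta")
    pillars = str(d / "pillars.json")
    sio.write_fasta(target.genome.sequences, scaffolds)
    sio.write_pillar_db(world.pillars, world.ancestral, pillars)
    config = PipelineConfig(scaffolds=scaffolds, pillars=pillars,
                            out=str(d / "out"), prefix="SMA", wgd="non")
    result = run_pipeline(config)
    return spec, world, target, result


@pytest.fixture(scope="session")
def frameshift_run(tmp_path_factory):
    """Shared run over a fixture with planted indels and simulated reads."""
    spec = FixtureSpec(seed=202, n_pillars=20, frameshift_count=8,
                       read_coverage=20.0, divergence=0.05)
    world = build_reference_world(spec)
    target = derive_target_genome(world)
    injected = inject_frameshifts_and_reads(target, spec)
    d = tmp_path_factory.mktemp("fs_run")
    scaffolds = str(d / "scaffolds.fasta")
    pillars = str(d / "pillars.json")
    reads = str(d / "reads.fasta")
    sio.write_fasta(injected.edited_genome.sequences, scaffolds)
    sio.write_pillar_db(world.pillars, world.ancestral, pillars)
    sio.write_fasta(injected.reads, reads)
    config = PipelineConfig(scaffolds=scaffolds, pillars=pillars,
                            reads=reads, fix_frameshifts="reads",
                            out=str(d / "out"), prefix="FSX", wgd="non")
    result = run_pipeline(config)
    return spec, world, target, injected, result, d
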