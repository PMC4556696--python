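import dataclasses

import pytest

from mirtronkit.hairpin_annotation import annotate
from mirtronkit.mapping import GenomeIndex, assign_to_introns, map_iterative
from mirtronkit.synthetic_data import (
    SimConfig,
    build_truth,
    default_manifest,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A compact simulation: 2 loci per subtype, modest depth."""
    return SimConfig(
        seed=11,
        n_bulk_genes=10,
        class_counts={
            "conventional": 2,
            "5p_tailed": 2,
            "3p_tailed": 2,
            "two_tailed": 2,
            "canonical": 2,
        },
        depth_per_library=8000,
        background_rate=1.0,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return build_truth(small_config)


@pytest.fixture(scope="session")
def small_manifest():
    return default_manifest()


@pytest.fixture(scope="session")
def small_reads(small_truth, small_manifest):
    return simulate_reads(small_truth, small_manifest)


@pytest.fixture(scope="session")
def small_summaries(small_truth, small_manifest, small_reads):
    batches, _ = small_reads
    lib_classes = {m.library_id: m.lib_class for m in small_manifest}
    index = GenomeIndex(small_truth.genome)
    aligned = []
    for lib_id, batch in batches.items():
        al, _ = map_iterative(batch, small_truth.genome, index=index)
        aligned.extend(al)
    return assign_to_introns(aligned, small_truth.introns, lib_classes)


@pytest.fixture(scope="session")
def small_calls(small_truth, small_summaries):
    return annotate(small_truth.genome, small_truth.introns, small_summaries)


def noiseless(config: SimConfig, **overrides) -> SimConfig:
    """A copy of config with all terminal phenomenology switched off."""
    defaults = dict(
        jitter5={0: 1.0},
        uridylation_prob=0.0,
        adenylation_prob=0.0,
        decapitation_prob=0.0,
        background_rate=0.0,
    )
    defaults.update(overrides)
    return dataclasses.replace(config, **defaults)
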