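import warnings

import numpy as np
import pytest

from msatmine import pipeline, simdata
from msatmine.config import PipelineConfig
from msatmine.repeat_scan import revcomp


@pytest.fixture(scope="session")
def discovery_run():
    """One seeded, error-free, 30x discovery run shared by the end-to-end
    tests: simulated genomes + reads + full pipeline result."""
    config = PipelineConfig(seed=1)
    sim_config = simdata.SimConfig(seed=1)
    genomes = simdata.simulate_genomes(sim_config)
    reads, origin = simdata.simulate_reads(
        genomes.haplotypes,
        coverage=sim_config.coverage,
        read_length=sim_config.read_length,
        error_rate=sim_config.error_rate,
        seed=101,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = pipeline.discover_markers(
            reads,
            config=config,
            validation_templates=genomes.haplotypes,
            individual_of=simdata.individual_of_read,
        )
    return {
        "config": config,
        "sim_config": sim_config,
        "genomes": genomes,
        "reads": reads,
        "origin": origin,
        "result": result,
    }


def match_cluster_to_locus(cluster, loci, anchor_k=12):
    """Assign a cluster to the planted locus whose flank anchors it carries,
    in either orientation; None if unmatched (spontaneous repeat)."""
    lookup = {}
    for locus in loci:
        for anchor in (
            locus.flank_left[-anchor_k:],
            locus.flank_right[:anchor_k],
            revcomp(locus.flank_right)[-anchor_k:],
            revcomp(locus.flank_left)[:anchor_k],
        ):
            lookup[anchor] = locus
    return lookup.get(cluster.consensus_left[-anchor_k:]) or lookup.get(
        cluster.consensus_right[:anchor_k]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20210326)
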