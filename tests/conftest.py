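import numpy as np
import pytest

from backsplice.reference import GenomeSource, TranscriptModel, TranscriptomeIndex
from backsplice.simulate import (
    SimulationConfig,
    sample_truth_junctions,
    simulate_reads,
    simulate_reference,
)

SMALL_SIM = SimulationConfig(n_genes=12, exons_per_gene=(3, 5),
                             n_ptes=15, n_canonical=15, coverage=6, seed=77)


@pytest.fixture(scope="session")
def small_sim():
    """Small seeded dataset: genome, transcriptome, truth and reads."""
    genome, transcriptome = simulate_reference(SMALL_SIM)
    rng = np.random.default_rng(123)
    truth = sample_truth_junctions(transcriptome, SMALL_SIM.n_ptes,
                                   SMALL_SIM.n_canonical, rng)
    reads = simulate_reads(truth, transcriptome, genome, SMALL_SIM,
                           np.random.default_rng(456))
    return {"config": SMALL_SIM, "genome": genome, "genome_src": GenomeSource(genome),
            "transcriptome": transcriptome, "truth": truth, "reads": reads}


@pytest.fixture()
def toy_transcriptome():
    """Hand-built two-gene transcriptome over an explicit genome string.

    GENEA|TX1 (+): exons [10,130), [330,510), [710,830) on chrT
    GENEB|TX1 (-): exons [1000,1150), [1350,1500) (transcript order reversed)
    """
    rng = np.random.default_rng(2024)
    seq = "".join(rng.choice(list("ACGT"), size=1600))
    genome = GenomeSource({"chrT": seq})
    tx_a = TranscriptModel("GENEA|TX1", "GENEA", "chrT", "+",
                           ((10, 130), (330, 510), (710, 830)))
    tx_b = TranscriptModel("GENEB|TX1", "GENEB", "chrT", "-",
                           ((1350, 1500), (1000, 1150)))
    return genome, TranscriptomeIndex([tx_a, tx_b])
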