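import numpy as np
import pytest

from tglocate.architecture import (
    InsertionArchitecture,
    apply_architecture,
    build_wt_reference,
)
from tglocate.genome import VectorConstruct
from tglocate.mapper import MapParams, SeedIndex
from tglocate.pairs import align_pairs
from tglocate.pipeline import RunConfig, simulate_stage
from tglocate.simulate import Genotype, ReadSimParams, simulate_reads

# Small-scale study conditions used throughout the unit tests: a 150 kb
# contig at scale 0.02 keeps the full architecture topology (two sub-sites,
# three deletions) while a run maps in ~1 s.
SMALL_CONTIG = 150_000
SMALL_SCALE = 0.02


def small_config(seed=0, genotype="HOM", **sim_kwargs) -> RunConfig:
    return RunConfig(
        seed=seed,
        genotype=genotype,
        contig_length=SMALL_CONTIG,
        architecture=InsertionArchitecture(scale=SMALL_SCALE),
        sim=ReadSimParams(**sim_kwargs) if sim_kwargs else ReadSimParams(),
    )


@pytest.fixture(scope="session")
def default_arch():
    return InsertionArchitecture()


@pytest.fixture(scope="session")
def small_arch():
    return InsertionArchitecture(scale=SMALL_SCALE)


@pytest.fixture(scope="session")
def small_truth_bundle(small_arch):
    """Wild-type reference, vector, transgenic haplotype and truth set."""
    ref = build_wt_reference(SMALL_CONTIG, small_arch, seed=1)
    vector = VectorConstruct.random(seed=2)
    tg, truth = apply_architecture(ref, vector, small_arch)
    return ref, vector, tg, truth


@pytest.fixture(scope="session")
def hom_run(small_truth_bundle, small_arch):
    """One small homozygous simulation mapped end to end (shared)."""
    ref, vector, tg, truth = small_truth_bundle
    params = ReadSimParams(seed=7)
    reads = simulate_reads(ref.contigs["chr1"], tg, Genotype.HOM, params)
    index = SeedIndex(ref.with_vector(vector).contigs, k=21)
    pairs = align_pairs(reads, index, MapParams())
    return {
        "ref": ref,
        "vector": vector,
        "tg": tg,
        "truth": truth,
        "reads": reads,
        "index": index,
        "pairs": pairs,
    }


@pytest.fixture(scope="session")
def wt_run(small_truth_bundle):
    ref, vector, tg, truth = small_truth_bundle
    params = ReadSimParams(seed=8)
    reads = simulate_reads(ref.contigs["chr1"], None, Genotype.WT, params)
    index = SeedIndex(ref.with_vector(vector).contigs, k=21)
    pairs = align_pairs(reads, index, MapParams())
    return {"ref": ref, "vector": vector, "truth": truth, "reads": reads,
            "index": index, "pairs": pairs}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
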