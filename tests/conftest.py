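import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from chlorotype import simulate as sim
from chlorotype.alignment import MultiAlignment


@pytest.fixture(scope="session")
def toy_alignment() -> MultiAlignment:
    #            0123456789
    return MultiAlignment(
        ["ref", "t2", "t3"],
        ["ACGTACGTAC",
         "ACCTA-GTAC",
         "ACCTACGAAC"],
        reference="ref",
    )


@pytest.fixture(scope="session")
def simulated() -> dict:
    """A scaled synthetic plastome alignment with planted truth events."""
    spec = sim.RootGenomeSpec(
        length=6_000,
        ssr_loci=[(500, "T", 12), (1_500, "AT", 6), (2_500, "T", 10),
                  (3_500, "TA", 7)],
        gene_intervals=[(4_000, 4_299, "+", "toyA")],
        long_indel_sites=[(5_200, 342), (5_700, 225)],
        seed=11,
    )
    root, annotation = sim.build_root_genome(spec)
    tree = sim.SimGenealogy(
        "((A:1,B:1):1,((C:1,D:1):1,(E:1,(F:1,G:1):1):1):1);"
    )
    model = sim.MutationModel(sub_rate=1.5e-3, ssr_step_rate=0.25,
                              indel_rate=0.6)
    aln, truth = sim.evolve_genomes(root, annotation, tree, model, seed=11)
    return {"spec": spec, "root": root, "annotation": annotation,
            "tree": tree, "model": model, "aln": aln, "truth": truth}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
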