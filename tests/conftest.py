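import pytest

from famprio.io_formats import read_annotations, read_pedigree, read_variants
from famprio.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """One default simulated family dataset, parsed back through the readers."""
    out = tmp_path_factory.mktemp("default_sim")
    sim = simulate_cohort(SimulationConfig(seed=11), out)
    cohort = read_pedigree(sim.pedigree_path)
    variants = read_variants(sim.vcf_path, cohort)
    annotations = read_annotations(sim.annotation_path)
    return sim, cohort, variants, annotations
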