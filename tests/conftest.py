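import numpy as np
import pytest
from hypothesis import settings

from kindred import (
    emit_genotype_likelihoods,
    simulate_pedigree_genotypes,
    simulate_reference_panel,
)
from kindred.genome import GeneticMap
from kindred.simulate import PedigreeSpec

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def two_pop_panel():
    """K=2 Balding-Nichols panel, S=10,000, F=0.1."""
    return simulate_reference_panel(2, 10_000, 0.1, seed=101)


@pytest.fixture(scope="session")
def autosome_map():
    """Full-genome scale map: 22 chromosomes, ~3,520 cM."""
    return GeneticMap.regular(2200, n_chrom=22, chrom_length_bp=160_000_000)


@pytest.fixture(scope="session")
def three_generation_cohort():
    """Grandparents, two sib parents with spouses, four cousins; one panel
    population; full-genome map; low-coverage GLs.  Supplies pairs of
    1st-3rd degree with exact truth."""
    S = 100_000
    gmap = GeneticMap.regular(S, n_chrom=22, chrom_length_bp=160_000_000)
    panel = simulate_reference_panel(1, S, 0.15, seed=41, gmap=gmap)
    q = np.array([1.0])
    founders = {x: q for x in ["GA", "GB", "SPa", "SPb"]}
    children = [
        ("P1", "GA", "GB"), ("P2", "GA", "GB"),
        ("C1", "P1", "SPa"), ("C2", "P1", "SPa"),
        ("C3", "P2", "SPb"), ("C4", "P2", "SPb"),
    ]
    spec = PedigreeSpec(founders=founders, children=children)
    haps, truth = simulate_pedigree_genotypes(panel, spec, seed=42)
    glm = emit_genotype_likelihoods(haps, gmap, 1.0, 0.005, seed=43)
    return {"panel": panel, "spec": spec, "haps": haps, "truth": truth, "gl": glm}
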