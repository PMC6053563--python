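import numpy as np
import pytest

from ssrpopgen.core import GenotypeDataset


def make_dataset(area_genotypes: dict[str, list[list[tuple[int, int]]]], loci=None):
    """Build a GenotypeDataset from {area: [[ (a,b) per locus ] per individual]}."""
    areas = list(area_genotypes)
    n_loci = len(next(iter(area_genotypes.values()))[0])
    loci = loci or [f"L{j + 1}" for j in range(n_loci)]
    individuals = {
        a: [f"{a}_{i + 1}" for i in range(len(g))] for a, g in area_genotypes.items()
    }
    calls = {a: np.array(g, dtype=np.int64) for a, g in area_genotypes.items()}
    return GenotypeDataset(areas=areas, individuals=individuals, loci=loci, calls=calls)


@pytest.fixture
def two_area_biallelic():
    """2 areas x 4 individuals x 1 biallelic locus; used by the WC oracle."""
    return make_dataset(
        {
            "P1": [[(1, 1)], [(1, 2)], [(1, 2)], [(2, 2)]],
            "P2": [[(1, 1)], [(1, 1)], [(1, 2)], [(1, 1)]],
        }
    )


@pytest.fixture
def single_area_hand():
    """One area, genotypes AA, AA, Aa at one locus (hand-computable)."""
    return make_dataset({"A": [[(1, 1)], [(1, 1)], [(1, 2)]]})
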