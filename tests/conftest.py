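import numpy as np
import pandas as pd
import pytest

from gma import ClassTable, LocusSpec, load_acp1


@pytest.fixture(scope="session")
def acp1():
    """Packaged ACP1 class table and locus (frequencies gene-counted from
    the observed class frequencies, baseline C)."""
    return load_acp1()


def random_unphased_locus(rng: np.random.Generator, m: int,
                          locus_id: str = "L1") -> LocusSpec:
    """A locus with Dirichlet allele frequencies summing to 1 exactly."""
    p = rng.dirichlet(np.ones(m) * 2.0)
    p = p / p.sum()
    alleles = [f"A{k + 1}" for k in range(m)]
    return LocusSpec(locus_id, alleles, freq_paternal=p, freq_maternal=p)


def random_phased_locus(rng: np.random.Generator, m: int,
                        locus_id: str = "L1") -> LocusSpec:
    pP = rng.dirichlet(np.ones(m) * 2.0)
    pM = rng.dirichlet(np.ones(m) * 2.0)
    alleles = [f"A{k + 1}" for k in range(m)]
    return LocusSpec(locus_id, alleles, freq_paternal=pP / pP.sum(),
                     freq_maternal=pM / pM.sum())


def random_class_values(rng: np.random.Generator, loci, phased=False):
    """A class table over all joint classes with random genotypic values."""
    from gma import joint_classes
    gdf = joint_classes(loci, phased)
    y = rng.normal(0.0, 10.0, size=len(gdf))
    return ClassTable(genotypes=gdf, frequency=np.ones(len(gdf)),
                      traits=pd.DataFrame({"y": y}))
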