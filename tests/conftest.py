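import numpy as np
import pytest

import magicgs as mg


@pytest.fixture(scope="session")
def panel305():
    """A full-size MAGIC panel: 305 RILs, 11 chromosomes x 50 SNPs."""
    return mg.simulate_magic_panel(n_rils=305, n_snps_per_chr=50, n_chr=11,
                                   seed=20)


@pytest.fixture(scope="session")
def tiny_panel():
    """A small panel for fast structural tests: 60 RILs, 3 x 20 SNPs."""
    return mg.simulate_magic_panel(n_rils=60, n_snps_per_chr=20, n_chr=3,
                                   seed=21)


@pytest.fixture(scope="session")
def oligogenic_trait(panel305):
    """Phenotype with three large QTL, a polygenic tail and mild epistasis."""
    arch = mg.simulate.large_effect_architecture(panel305, seed=22)
    pheno = mg.simulate_phenotypes(panel305, arch, seed=23)
    y = pheno.values_for(panel305.ril_ids, environment="env1")
    return arch, pheno, y


def make_genotype(codes, pos=None, chrom=None):
    """Hand-built GenotypeMatrix for toy examples."""
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    return mg.GenotypeMatrix(
        codes=codes,
        snp_ids=np.array([f"s{j}" for j in range(m)], dtype=object),
        ril_ids=np.array([f"r{i}" for i in range(n)], dtype=object),
        chrom=np.array(["chr1"] * m if chrom is None else chrom, dtype=object),
        pos_cm=np.arange(m, dtype=float) if pos is None else np.asarray(pos, float),
    )
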