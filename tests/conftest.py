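import numpy as np
import pytest

import nagwas as ng


@pytest.fixture(scope="session")
def small_cohort() -> ng.Cohort:
    """A small family cohort with a recessive causal variant at v000001."""
    cfg = ng.SimConfig(n_families=60, n_variants=120, seed=11)
    causal = [ng.CausalSpec("v000001", "recessive", beta=0.086, freq=0.548)]
    return ng.simulate_cohort(cfg, causal=causal, name="small")


@pytest.fixture(scope="session")
def pdss2_table():
    return ng.load_pdss2_locus()


@pytest.fixture(scope="session")
def founder_genotypes() -> ng.GenotypeMatrix:
    """Unrelated Hardy-Weinberg founders (one-person 'families')."""
    cfg = ng.SimConfig(n_families=200, sibs_min=1, sibs_max=1,
                       n_variants=800, seed=5)
    ped = ng.simulate_pedigree(cfg)
    founders = [i for i, ind in enumerate(ped.individuals) if ind.is_founder]
    gm = ng.simulate_genotypes(ped, cfg, store_gp=False)
    return gm.subset_samples(founders)


def align_kinship(kin: ng.KinshipMatrix, samples) -> ng.KinshipMatrix:
    idx = {s: i for i, s in enumerate(kin.samples)}
    order = [idx[s] for s in samples]
    return ng.KinshipMatrix(list(samples), kin.K[np.ix_(order, order)])


@pytest.fixture(scope="session")
def fitted_small(small_cohort):
    """Prepared phenotypes, design, genomic kinship and polygenic fit."""
    pheno, _ = ng.apply_exclusions(small_cohort.phenotypes)
    gidx = {s: i for i, s in enumerate(small_cohort.genotypes.samples)}
    gm = small_cohort.genotypes.subset_samples(
        [gidx[s] for s in pheno["sample"]])
    y, X = ng.build_design(pheno)
    kin = align_kinship(ng.estimate_kinship(small_cohort.genotypes),
                        list(pheno["sample"]))
    fit = ng.fit_polygenic(y, X, kin)
    return gm, pheno, kin, fit
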