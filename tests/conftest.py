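import numpy as np
import pytest
from hypothesis import settings

import admixkit as ak
from admixkit.model import build_migration_schedule

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

BASE_PROPS = {"EUR": 0.65, "NAT": 0.30, "AFR": 0.05}


@pytest.fixture(scope="session")
def chroms10():
    return ak.ChromosomeSet.uniform(10, 150.0)


@pytest.fixture(scope="session")
def chroms_small():
    return ak.ChromosomeSet.uniform(4, 100.0)


@pytest.fixture(scope="session")
def base_schedule():
    """Founding EUR/NAT admixture 12 generations ago with an AFR pulse at
    generation 6, pinned to the standard proportions."""
    return build_migration_schedule("base", {"t0": 12, "t_afr": 6}, BASE_PROPS)


@pytest.fixture(scope="session")
def small_cohort(base_schedule, chroms_small):
    return ak.simulate_pedigree_tracts(base_schedule, chroms_small, 30, seed=11)


@pytest.fixture(scope="session")
def painted_cohort(chroms_small):
    """50/50 EUR/NAT cohort with alleles painted at FST 0.1."""
    sch = ak.MigrationSchedule.from_pulses(("EUR", "NAT"), 8, {"EUR": 0.5, "NAT": 0.5})
    cohort = ak.simulate_pedigree_tracts(sch, chroms_small, 25, seed=21)
    freqs = ak.draw_ancestral_frequencies(
        4000, 2, 0.1, chroms_small, seed=22, populations=("EUR", "NAT")
    )
    return ak.paint_haplotypes(cohort, freqs, seed=23)


@pytest.fixture(scope="session")
def reference_panel(chroms_small, painted_cohort):
    """Pure EUR and NAT reference haplotypes painted from the same
    ancestral frequencies as the admixed cohort."""
    freqs = painted_cohort.frequencies
    mats = []
    for i, pop in enumerate(("EUR", "NAT")):
        sch = ak.MigrationSchedule.from_pulses(("EUR", "NAT"), 2, {pop: 1.0})
        rc = ak.simulate_pedigree_tracts(sch, chroms_small, 15, seed=31 + i)
        ak.paint_haplotypes(rc, freqs, seed=41 + i)
        rc.labels = [pop] * rc.n_individuals
        m = rc.haplotype_matrix(is_reference=True)
        m.haplotype_ids = [f"{pop}_{h}" for h in m.haplotype_ids]
        mats.append(m)
    return ak.MaskedHaplotypeMatrix(
        haplotype_ids=mats[0].haplotype_ids + mats[1].haplotype_ids,
        locus_ids=mats[0].locus_ids,
        chrom=mats[0].chrom,
        pos_cM=mats[0].pos_cM,
        alleles=np.vstack([m.alleles for m in mats]),
        populations=mats[0].populations + mats[1].populations,
        is_reference=np.ones(sum(len(m.haplotype_ids) for m in mats), bool),
    )
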