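"""Shared fixtures: the study family and small genomic objects."""

import numpy as np
import pytest
from hypothesis import settings

from famase.core import FamilyDesign, GeneModel, GenotypeClass as G, VariantRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def family() -> FamilyDesign:
    """Two parents, eight offspring, four replicate samples each."""
    offspring = tuple(f"offspring_{i}" for i in range(1, 9))
    individuals = ("mother", "father") + offspring
    return FamilyDesign(
        mother_id="mother",
        father_id="father",
        offspring_ids=offspring,
        sample_map={
            f"{ind}_r{k}": ind for ind in individuals for k in range(1, 5)
        },
    )


@pytest.fixture
def gene() -> GeneModel:
    return GeneModel(
        gene_id="g1",
        chrom="chr1",
        start=100_000,
        end=120_000,
        strand="+",
        exons=((100_000, 103_000), (108_000, 111_000), (117_000, 120_000)),
    )


def make_variant(family, mother, father, offspring, pos=1000, chrom="chr1",
                 ref="A", alt="G", **kw) -> VariantRecord:
    gts = {family.mother_id: mother, family.father_id: father}
    gts.update(dict(zip(family.offspring_ids, offspring)))
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                         genotypes=gts, **kw)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_250_101)
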