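import numpy as np
import pytest

from germdiv import (
    AccessionRecord,
    TraitDescriptor,
    TraitMatrix,
    VariantGenSpec,
    gen_variants,
)

PLANT_TYPE = TraitDescriptor(
    "plant type", "qualitative",
    levels={1: "vine type", 2: "half-vine type", 3: "upright"})
GROWTH_HABIT = TraitDescriptor(
    "growth habit", "qualitative",
    levels={1: "infinite growth", 2: "finite growth"})
PLANT_HEIGHT = TraitDescriptor("plant height", "quantitative", units="cm")


@pytest.fixture
def coding():
    return [PLANT_TYPE, GROWTH_HABIT, PLANT_HEIGHT]


@pytest.fixture
def small_matrix(coding):
    rng = np.random.default_rng(42)
    records = [
        AccessionRecord(
            str(i + 1),
            {
                "plant type": int(rng.integers(1, 4)),
                "growth habit": int(rng.integers(1, 3)),
                "plant height": float(rng.normal(37.9, 10.3)),
            },
        )
        for i in range(20)
    ]
    return TraitMatrix(coding, records, provenance="test fixture")


@pytest.fixture(scope="session")
def toy_variants(tmp_path_factory):
    """A small seeded toy genome + VCF + truth table shared across tests."""
    outdir = tmp_path_factory.mktemp("toyvar")
    spec = VariantGenSpec(n_snps=2000, n_samples=2, seed=11)
    out = gen_variants(spec, outdir)
    out["spec"] = spec
    return out


def merge_matrices(a: TraitMatrix, b: TraitMatrix) -> TraitMatrix:
    """Combine two matrices over the same accession ids into one."""
    assert a.accession_ids == b.accession_ids
    records = [
        AccessionRecord(ra.accession_id, {**ra.values, **rb.values})
        for ra, rb in zip(a.records, b.records)
    ]
    return TraitMatrix(a.descriptors + b.descriptors, records,
                       provenance=a.provenance)
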