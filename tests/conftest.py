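import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tissueshift as ts

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tiny_matrix() -> ts.ExpressionMatrix:
    """Hand-sized 4-gene x 3-tissue matrix with one zero cell."""
    return ts.ExpressionMatrix(
        gene_ids=["ACTB", "GFAP", "MYH7", "INS"],
        tissue_ids=["Brain - Cortex", "Heart - Left Ventricle", "Pancreas"],
        values=np.array(
            [
                [10.0, 5.0, 2.0],
                [50.0, 0.0, 1.0],
                [1.0, 80.0, 3.0],
                [0.5, 2.0, 90.0],
            ]
        ),
    )


@pytest.fixture
def planted_cfg() -> ts.SyntheticConfig:
    """One strongly enriched disease set targeting a single brain tissue."""
    return ts.SyntheticConfig(
        disease_sets=[
            ts.DiseaseSpec(
                name="planted",
                size=100,
                target_tissues=["Brain - Amygdala"],
                enrichment_fold=50.0,
            )
        ],
        seed=11,
    )


@pytest.fixture
def small_null_cfg() -> ts.SyntheticConfig:
    """Reduced-scale null: no enrichment, 12 tissues, 400 genes."""
    return ts.SyntheticConfig(
        n_genes=400,
        tissue_names=list(ts.GTEX_LIKE_TISSUES[:12]),
        disease_sets=[
            ts.DiseaseSpec(
                name="null",
                size=30,
                target_tissues=["Bladder"],
                enrichment_fold=1.0,
            )
        ],
        seed=3,
    )
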