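import pytest

from paneltier.cnv_purity import build_reference
from paneltier.datasets import load_reference_cohort
from paneltier.synthetic_cohort import generate_panel, simulate_normal_profile
from paneltier.tiering import classify_patient


@pytest.fixture(scope="session")
def small_panel():
    """30 genes x 4 exons x 150 bp synthetic panel (18 kb exonic)."""
    return generate_panel(n_genes=30, exons_per_gene=4, exon_length=150, seed=1)


@pytest.fixture(scope="session")
def noise_free_reference(small_panel):
    normals = [
        simulate_normal_profile(small_panel, base_depth=500, noise_sd=0.0, seed=100 + i)
        for i in range(3)
    ]
    return build_reference(normals, "FF")


@pytest.fixture()
def reference_cohort():
    """The bundled 55-patient cohort, tiered."""
    cases, kb = load_reference_cohort()
    for case in cases:
        case.assignments, case.best_tier = classify_patient(case, kb)
        case.processed = True
    return cases, kb
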