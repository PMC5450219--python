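import pytest

from bhlh_survey.domain_profile import build_profile, default_regions, scan_collection
from bhlh_survey.synthetic_data import (
    ExpressionSpec, FamilySpec, generate_expression, generate_family,
    true_domain_alignment,
)


@pytest.fixture(scope="session")
def small_family():
    """A 5-subfamily, zero-noise family with planted truth."""
    spec = FamilySpec(n_subfamilies=5, members_per_subfamily=8,
                      per_position_substitution_rate=0.0, seed=11)
    records, truth = generate_family(spec)
    return spec, records, truth


@pytest.fixture(scope="session")
def small_profile(small_family):
    _, records, truth = small_family
    return build_profile(true_domain_alignment(records, truth))


@pytest.fixture(scope="session")
def small_hits(small_family, small_profile):
    _, records, _ = small_family
    hits, missing = scan_collection(small_profile, records)
    assert not missing
    return hits


@pytest.fixture(scope="session")
def small_regions(small_profile):
    return default_regions(small_profile)


@pytest.fixture(scope="session")
def expression_data():
    """A 60-gene, 4-tissue block-structured expression dataset."""
    spec = ExpressionSpec(n_genes=60, n_tissues=4, samples_per_tissue=3,
                          noise_sd=0.3, seed=7)
    matrix, ref_ids, qpcr, truth_blocks = generate_expression(spec)
    return spec, matrix, ref_ids, qpcr, truth_blocks
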