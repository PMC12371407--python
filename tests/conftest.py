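import numpy as np
import pytest

from gvpop.variant_filtering import VariantMatrix


def build_matrix(
    genotypes,
    positions=None,
    variant_class=None,
    depths=None,
    ref=None,
    alt=None,
    sample_ids=None,
):
    """Construct a VariantMatrix from a genotype array with sane defaults."""
    g = np.asarray(genotypes, dtype=np.int16)
    n_sites, n_samples = g.shape
    if positions is None:
        positions = np.arange(n_sites) * 10
    if variant_class is None:
        variant_class = np.array(["SNP"] * n_sites, dtype=object)
    else:
        variant_class = np.asarray(variant_class, dtype=object)
    if depths is None:
        depths = np.full((n_sites, n_samples, 2), 50, dtype=np.int32)
        depths[:, :, 1] = np.where(g > 0, 50, 0)
        depths[:, :, 0] = np.where(g == 0, 50, 0)
    if ref is None:
        ref = ["A"] * n_sites
    if alt is None:
        alt = [
            tuple("CGT"[: max(int(g[i].max(initial=0)), 1)]) for i in range(n_sites)
        ]
    if sample_ids is None:
        sample_ids = [f"S{j:03d}" for j in range(n_samples)]
    return VariantMatrix(
        positions=np.asarray(positions, dtype=np.int64),
        ref=ref,
        alt=alt,
        variant_class=variant_class,
        genotypes=g,
        depths=np.asarray(depths, dtype=np.int32),
        sample_ids=sample_ids,
    )


@pytest.fixture
def matrix_builder():
    return build_matrix


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured synthetic cohort shared across tests."""
    from gvpop.synthetic_data import SimConfig, simulate_cohort

    cfg = SimConfig(
        genome_length=20_000,
        n_years=2,
        reservoir_size=20,
        year_pool_size=10,
        reservoir_mutation_rate=2e-3,
        founder_count_per_wave=(10, 4, 2),
        hosts_per_wave=4,
        n_orfs=20,
        n_hr_regions=3,
        total_isolates=None,
        seed=7,
    )
    return simulate_cohort(cfg)
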