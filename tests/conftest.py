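import pytest

from karyoscope import presets
from karyoscope.synthetic import StrainConfig


@pytest.fixture(scope="session")
def chrom_lengths():
    """Full Mb-scale chromosome lengths (15 chromosomes)."""
    return presets.CHROMOSOME_LENGTHS


@pytest.fixture(scope="session")
def small_lengths():
    """Scaled-down chromosomes for fast simulations (15 x 200 kb)."""
    return [200_000] * 15


def make_strain(strain_id, copies, seed=0, **kw):
    defaults = dict(base_depth=50.0, dispersion=0.1, outlier_fraction=0.02)
    defaults.update(kw)
    return StrainConfig.homokaryon(strain_id, copies, seed=seed, **defaults)


@pytest.fixture
def l7_assembly():
    """L7-plan synthetic assembly with its truth table (seed 42)."""
    from karyoscope.synthetic import generate_assembly

    truth = presets.l7_assembly_truth()
    records, table = generate_assembly(truth, seed=42)
    return records, table
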