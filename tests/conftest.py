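import numpy as np
import pytest

from pollenkiller.io import default_config_path, load_systems_config
from pollenkiller.model_core import KillerSystem, LocusDef, Role


@pytest.fixture(scope="session")
def config():
    return load_systems_config(default_config_path())


@pytest.fixture(scope="session")
def s35_locus():
    return LocusDef(name="S35", chrom="chr1", pos_bp=3_060_000, role=Role.KILLER)


@pytest.fixture(scope="session")
def ink_locus():
    return LocusDef(name="INK", chrom="chr5", pos_bp=1_700_000, role=Role.PARTNER)


@pytest.fixture(scope="session")
def s24_locus():
    return LocusDef(name="S24", chrom="chr5", pos_bp=1_350_000, role=Role.KILLER)


@pytest.fixture(scope="session")
def efs_locus():
    return LocusDef(name="EFS", chrom="chr2", pos_bp=24_000_000, role=Role.PARTNER)


@pytest.fixture(scope="session")
def ink_s35(s35_locus, ink_locus):
    """Activator-gated killer with survival matching k = 0.89."""
    return KillerSystem(
        killer=s35_locus,
        partner=ink_locus,
        partner_mode="activator",
        targeted_allele="J",
        survival_s=0.1236,
    )


@pytest.fixture(scope="session")
def efs_s24(s24_locus, efs_locus):
    """Suppressor-gated killer."""
    return KillerSystem(
        killer=s24_locus,
        partner=efs_locus,
        partner_mode="suppressor",
        targeted_allele="J",
        survival_s=0.05,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240321)
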