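import numpy as np
import pytest

from potlip import (
    FattyAcidConcentration,
    SourceClass,
    SourceGroup,
    default_scenario,
    end_to_end,
)


@pytest.fixture(scope="session")
def bundle():
    """One synthetic study-shaped dataset shared across tests."""
    return end_to_end(default_scenario(seed=42))


@pytest.fixture(scope="session")
def groups(bundle):
    from potlip import fit_all_groups

    return fit_all_groups(bundle.reference_fats)


@pytest.fixture(scope="session")
def classified(bundle, groups):
    from potlip import classify_samples

    return classify_samples(bundle.sherds, groups)


def make_group(cls, mean, cov, n=30, conc=None):
    conc = conc or FattyAcidConcentration(25.0, 25.0, 0.0, 0.0)
    return SourceGroup(
        source_class=cls, mean=np.asarray(mean, float),
        cov=np.asarray(cov, float), n=n, conc=conc,
    )


@pytest.fixture
def two_source_pair():
    """Two well-separated sources with equal concentrations and nearly
    point-mass signatures: the analytic interpolation oracle applies."""
    tiny = np.eye(2) * 1e-8
    g1 = make_group(SourceClass.RUMINANT_DAIRY, (-32.0, -36.0), tiny)
    g2 = make_group(SourceClass.NON_RUMINANT, (-24.0, -24.0), tiny)
    return [g1, g2]
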