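import numpy as np
import pytest

from isofoodweb.isotopes import GroupSummary, IsotopeMeasurement, SampleRecord
from isofoodweb.mixing import MeasurementError, SourceSet, TrophicEnrichment
from isofoodweb.synthetic import load_fixture


@pytest.fixture(scope="session")
def fixture_table():
    return load_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20240229)


def make_sample(sample_id, d13C, d15N, d34S=None, habitat="EEM",
                stratum="source", taxon="test", **kw):
    return SampleRecord(
        sample_id=sample_id, taxon=taxon, habitat=habitat, stratum=stratum,
        measurement=IsotopeMeasurement(delta13C=d13C, delta15N=d15N,
                                       delta34S=d34S, **kw))


def make_group(group_id, n, means, sds=None, label=None):
    sds = sds if sds is not None else {k: 1.0 for k in means}
    return GroupSummary(group_id=group_id, label=label or group_id, n=n,
                        means=means, sds=sds)


@pytest.fixture
def two_source_1d():
    """Two sources 20‰ apart on one isotope, no TEF, tiny errors."""
    sources = SourceSet(("left", "right"), ("d13C",),
                        np.array([[-30.0], [-10.0]]),
                        np.array([[1.0], [1.0]]))
    tef = TrophicEnrichment(("d13C",), np.array([0.0]), np.array([0.0]))
    meas = MeasurementError(("d13C",), np.array([0.1]))
    return sources, tef, meas


@pytest.fixture
def three_sources_2d():
    """Three well-separated sources on two isotopes (pairwise >= 10‰)."""
    sources = SourceSet(
        ("terrestrial", "marsh", "delta"), ("d13C", "d15N"),
        np.array([[-30.0, 0.0], [-20.0, 10.0], [-10.0, 0.0]]),
        np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]]))
    tef = TrophicEnrichment(("d13C", "d15N"), np.array([0.5, 2.0]),
                            np.array([0.2, 0.3]))
    meas = MeasurementError(("d13C", "d15N"), np.array([0.04, 0.07]))
    return sources, tef, meas
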