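import numpy as np
import pytest

from isomix.io import MixtureData, SourceData, as_fixed_sources, zero_discrimination
from isomix.model import ErrorSpec, ModelSpec, TracerDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_summary_sources(means, sds, n=25, names=None, tracers=None, conc=None):
    means = np.atleast_2d(np.asarray(means, dtype=float))
    k, j = means.shape
    return SourceData(
        treatment="summary",
        source_names=names or [f"s{i+1}" for i in range(k)],
        means=means,
        sds=np.atleast_2d(np.asarray(sds, dtype=float)),
        sample_sizes=np.full(k, n),
        tracer_names=tracers or [f"t{i+1}" for i in range(j)],
        concentrations=conc,
    )


def make_fixed_dataset(y, source_means, source_sds, tracers=None):
    """Small fixed-source dataset with no covariates."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    sources = as_fixed_sources(make_summary_sources(source_means, source_sds, tracers=tracers))
    mixture = MixtureData(values=y, tracer_names=list(sources.tracer_names))
    return TracerDataset(mixture=mixture, sources=sources)


@pytest.fixture
def sources_3x2():
    return make_summary_sources(
        means=[[-20.0, 2.0], [-12.0, 8.0], [-4.0, 14.0]],
        sds=[[1.0, 0.8], [1.2, 1.0], [0.9, 1.1]],
    )


@pytest.fixture
def toy_fixed_dataset(rng):
    """10 consumers, K=2, J=1, fixed sources."""
    y = rng.normal(-15.0, 1.5, size=(10, 1))
    return make_fixed_dataset(y, [[-20.0], [-10.0]], [[1.0], [1.5]])
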