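"""Shared fixtures: one fully processed default phantom, reused suite-wide.

The default-field phantom (256 × 256 µm, 1000 frames at 300 Hz) takes a few
seconds to simulate, so scene, stack, dynamic image and segmentations are
session-scoped; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

from dffoct.dyncontrast import AcquisitionParams, compute_dffoct, compute_static
from dffoct.phantom import PhantomSpec, build_scene, simulate_timestack
from dffoct.quantify import (
    classify_by_area,
    measure_regions,
    segment_ganglia,
    segment_nuclei,
)


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec(seed=1)


@pytest.fixture(scope="session")
def default_scene(default_spec):
    return build_scene(default_spec)


@pytest.fixture(scope="session")
def default_acq() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def default_stack(default_scene, default_spec, default_acq):
    return simulate_timestack(default_scene, default_spec, default_acq)


@pytest.fixture(scope="session")
def default_dynamic(default_stack, default_acq):
    return compute_dffoct(default_stack, default_acq)


@pytest.fixture(scope="session")
def default_static(default_stack):
    return compute_static(default_stack)


@pytest.fixture(scope="session")
def default_ganglia(default_static, default_dynamic):
    return segment_ganglia(default_static, default_dynamic)


@pytest.fixture(scope="session")
def default_nucleus_labels(default_dynamic, default_ganglia):
    return segment_nuclei(default_dynamic, default_ganglia)


@pytest.fixture(scope="session")
def default_records(default_nucleus_labels, default_dynamic):
    records = measure_regions(default_nucleus_labels, default_dynamic)
    return classify_by_area(records)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
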