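import numpy as np
import pytest

from polkin import changepoint, pipeline, synthgen


@pytest.fixture(scope="session")
def truth():
    return synthgen.make_ground_truth("adic-like", 1)


@pytest.fixture(scope="session")
def small_spec():
    """A short, cheap trace spec used by trace-level tests."""
    return synthgen.TraceSpec(n_frames=1200, bleach_time=11.0)


@pytest.fixture(scope="session")
def thresholds():
    """Shared Monte-Carlo detection-threshold cache (expensive to build)."""
    return changepoint.ThresholdTable(confidence=0.95, n_null=400)


@pytest.fixture(scope="session")
def small_traces(truth, small_spec):
    return pipeline.simulate_condition(truth, None, 0.0, 10, small_spec, seed=11)


@pytest.fixture(scope="session")
def analyzed_condition(truth, small_traces, thresholds):
    cfg = pipeline.PipelineConfig(seed=1)
    return pipeline.analyze_condition(small_traces, cfg, thresholds)
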