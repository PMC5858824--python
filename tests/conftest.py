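import pytest

from ltbca.fixtures import make_fixture_set, preset_config
from ltbca.scenario import build_model, compute_bias_for, load_scenario


def _inputs(preset: str, tmp_path_factory):
    outdir = tmp_path_factory.mktemp(f"fx_{preset}")
    paths = make_fixture_set(preset_config(preset, seed=1), outdir)
    return build_model(load_scenario(paths["scenario"]))


@pytest.fixture(scope="session")
def inputs_biased(tmp_path_factory):
    """Model inputs for the default differential-screening study conditions."""
    return _inputs("biased", tmp_path_factory)


@pytest.fixture(scope="session")
def inputs_null(tmp_path_factory):
    """Model inputs with identical screening behavior in both strata."""
    return _inputs("null", tmp_path_factory)


@pytest.fixture(scope="session")
def bias_biased(inputs_biased):
    return compute_bias_for(inputs_biased)
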