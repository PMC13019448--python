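import pathlib

import pytest

from bstkit.fixtures import feedback_pathway_model

EXAMPLES = pathlib.Path(__file__).resolve().parent.parent / "examples"


@pytest.fixture(scope="session")
def examples_dir() -> pathlib.Path:
    return EXAMPLES


@pytest.fixture()
def feedback():
    """Fresh feedback-pathway model and its pulse schedule."""
    return feedback_pathway_model()
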