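import logging

import pytest

from spherolipid.synthgen import GeneratorConfig, generate_lipidome


@pytest.fixture(autouse=True)
def _quiet_standard_fallback_log():
    """Silence the internal-standard fallback WARN chatter in tests."""
    logger = logging.getLogger("spherolipid.quantify")
    old = logger.level
    logger.setLevel(logging.ERROR)
    yield
    logger.setLevel(old)


@pytest.fixture(scope="session")
def paper_table():
    """One paper-preset synthetic peak table shared across tests."""
    logging.getLogger("spherolipid.quantify").setLevel(logging.ERROR)
    table, truth = generate_lipidome(GeneratorConfig(), seed=11)
    return table, truth
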