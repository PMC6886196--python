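import pytest

from pcomtext.textprep import default_stopwords


@pytest.fixture(scope="session")
def stopwords():
    return default_stopwords()
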