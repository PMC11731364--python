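import pytest

from massaudit.diagnostics import DiagnosticConfig
from massaudit.extraction import AMMRecord, SourceLocation


@pytest.fixture
def config():
    return DiagnosticConfig()


@pytest.fixture
def make_record():
    """Build an AMMRecord directly, bypassing text extraction."""

    loc = SourceLocation("synthetic.txt", 1)

    def _make(formula, ion, calcd, found, flags=()):
        raw = f"HRMS m/z: {ion} Calcd for {formula} {calcd}; Found {found}"
        return AMMRecord(raw, formula, ion, calcd, found, loc, tuple(flags))

    return _make
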