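import os
import stat
import textwrap

import pytest
from hypothesis import HealthCheck, settings

import molevo as m

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def consistent_panel():
    """Small clean panel under one nomenclature (session-cached)."""
    return m.make_hmtdna_panel(m.PanelSpec(n_records=12, seed=7))


@pytest.fixture(scope="session")
def refseq():
    return m.make_hmtdna_refseq(7)


@pytest.fixture
def write_stub(tmp_path):
    """Factory writing a small executable python script, for driving the
    dispatcher without any real external tool."""

    def _write(name: str, body: str) -> str:
        path = tmp_path / name
        path.write_text("#!/usr/bin/env python3\n" + textwrap.dedent(body))
        path.chmod(path.stat().st_mode | stat.S_IXUSR | stat.S_IXGRP | stat.S_IXOTH)
        return str(path)

    return _write
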