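import pytest

from imf.popgen import GenotypeCounts


@pytest.fixture(scope="session")
def sth_counts() -> GenotypeCounts:
    """Purebred Small-tail Han cohort: 6 CC / 12 CT / 7 TT, n=25."""
    return GenotypeCounts("C1146T", "STH", 6, 12, 7)


@pytest.fixture(scope="session")
def f1_counts() -> GenotypeCounts:
    """Suffolk x STH F1 cohort: 12 CC / 14 CT / 4 TT, n=30."""
    return GenotypeCounts("C1146T", "SFK x STH", 12, 14, 4)
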