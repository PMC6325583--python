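import pytest

from plastidlabel import FragmentSpec


@pytest.fixture
def galactose() -> FragmentSpec:
    return FragmentSpec("galactose", 6, 6)


@pytest.fixture
def glycerol() -> FragmentSpec:
    return FragmentSpec("glycerol", 3, 3)


@pytest.fixture
def palmitate_acetate() -> FragmentSpec:
    # 16:0 under [2-13C]acetate labeling: only the 8 even carbons labelable
    return FragmentSpec("16:0", 16, 8)
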