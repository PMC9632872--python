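import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ssfold import (
    DisulfideFixtureSpec,
    HelixSpec,
    build_disulfide_fixture,
    build_ideal_helix,
)

#: directory where a user with network access can place the deposited
#: coordinate files referenced by the printed-value checks (see README)
EXTERNAL_DATA = Path(__file__).resolve().parents[1] / "data" / "external"


@pytest.fixture
def ideal_ca_helix():
    return build_ideal_helix(HelixSpec(n_res=12))


@pytest.fixture
def backbone_helix():
    return build_ideal_helix(HelixSpec(n_res=12), full_backbone=True)


@pytest.fixture
def ss_fixture():
    spec = DisulfideFixtureSpec(chi1=-60, chi1p=-60, chi2=80, chi2p=80, chi3=95)
    return build_disulfide_fixture(spec), spec
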