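import numpy as np
import pytest

from papillastats import (
    BundleGenConfig,
    CellRegion,
    PapillaGenConfig,
    generate_bundles,
    generate_papilla_lattice,
)


@pytest.fixture
def region():
    """10 x 10 um paradermal window, the scale of one epidermal cell."""
    return CellRegion(width=10000.0, height=10000.0)


@pytest.fixture
def lattice(region):
    """Jitter-free papilla lattice at the measured 1.5 um pitch."""
    return generate_papilla_lattice(PapillaGenConfig(region=region), seed=0)


@pytest.fixture
def jittered_cell(region):
    """One synthetic cell: jittered papillae + attached bundle population."""
    papillae = generate_papilla_lattice(
        PapillaGenConfig(region=region, jitter_sd=150.0), seed=11
    )
    bundles = generate_bundles(
        papillae,
        region,
        BundleGenConfig(n_bundles=27, assoc_fraction=0.6),
        seed=12,
    )
    return papillae, bundles
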