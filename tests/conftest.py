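import pytest

from citrusvol import (
    CultivarRegistry,
    LadDatabase,
    OrchardGeometry,
    ProductRegistry,
    TargetDatabase,
    load_fixture,
)


@pytest.fixture(scope="session")
def targets_db():
    return TargetDatabase.load()


@pytest.fixture(scope="session")
def lad_db():
    return LadDatabase.load()


@pytest.fixture(scope="session")
def products_db():
    return ProductRegistry.load()


@pytest.fixture(scope="session")
def cultivars_db():
    return CultivarRegistry.load()


@pytest.fixture(scope="session")
def orchards():
    """Trial-orchard geometries keyed by orchard id."""
    t3 = load_fixture("T3")
    return {
        r.orchard_id: OrchardGeometry(
            h=r.h, d_across=r.d_across, d_along=r.d_along,
            sp_tree=r.sp_tree, sp_row=r.sp_row,
        )
        for r in t3.itertuples()
    }
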