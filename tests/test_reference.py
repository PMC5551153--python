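"""Reference databases: lookups, validation, round-trips."""

import pytest
import yaml

from citrusvol import (
    DatabaseError,
    LadDatabase,
    TargetDatabase,
    UnknownProductError,
    UnknownTargetError,
)


@pytest.mark.parametrize(
    "name, f_target, app_class",
    [
        ("California red scale", 1.0, "internal"),
        ("Aonidiella aurantii", 1.0, "internal"),  # alias
        ("Two-spotted spider mite", 1.0, "internal"),
        ("Pezothrips kellyanus", 0.75, "intermediate"),
        ("cotton aphid", 0.75, "intermediate"),
        ("Mediterranean fruit fly", 0.49, "external"),
        ("MEDFLY", 0.49, "external"),  # case-insensitive alias
    ],
)
def test_target_lookup(targets_db, name, f_target, app_class):
    spec = targets_db.lookup(name)
    assert spec.f_target == f_target
    assert spec.application_class.value == app_class


def test_f_target_determined_by_class_only(targets_db):
    assert {t.f_target for t in targets_db.targets.values()} == {1.0, 0.75, 0.49}
    for t in targets_db.targets.values():
        assert t.f_target == {"internal": 1.0, "intermediate": 0.75,
                              "external": 0.49}[t.application_class.value]


@pytest.mark.parametrize(
    "name, warning",
    [
        ("Mediterranean fruit fly", "bait_treatment"),
        ("Cottony cushion scale", "no_authorized_products"),
        ("Phytophthora foot rot", "trunk_application"),
    ],
)
def test_special_target_warnings(targets_db, name, warning):
    assert warning in targets_db.lookup(name).warnings


def test_unknown_target_suggests_near_matches(targets_db):
    with pytest.raises(UnknownTargetError) as err:
        targets_db.lookup("california red scal")
    assert any("california" in s for s in err.value.suggestions)


@pytest.mark.parametrize(
    "group, pruning, lad",
    [
        ("medium", "normal", 3.7),
        ("low", "severe", 2.5),
        ("high", "without_pruning", 5.0),
    ],
)
def test_lad_lookup(lad_db, group, pruning, lad):
    assert lad_db.lookup(group, pruning) == lad


def test_lad_invalid_enum_lists_allowed_values(lad_db):
    with pytest.raises(DatabaseError, match="low"):
        lad_db.lookup("dense", "normal")
    with pytest.raises(DatabaseError, match="severe"):
        lad_db.lookup("low", "heavy")


def test_lad_monotonicity_violation_rejected(tmp_path, lad_db):
    df = lad_db.to_frame()
    df.loc[(df.cultivar_group == "medium") & (df.pruning == "normal"), "lad"] = 3.0
    bad = tmp_path / "lad.csv"
    df.to_csv(bad, index=False)
    with pytest.raises(DatabaseError, match="increasing"):
        LadDatabase.load(bad)


@pytest.mark.parametrize(
    "product, deposit, moa",
    [
        ("chlorpyrifos", 3.41, "contact"),
        ("mineral oil", 4.72, "suffocating"),
        ("spirotetramat", 3.41, "contact"),
        ("suffocating", 4.72, "suffocating"),  # class name accepted directly
    ],
)
def test_product_lookup(products_db, product, deposit, moa):
    spec = products_db.lookup(product)
    assert spec.deposit == deposit
    assert spec.moa_class.value == moa


def test_unknown_product_needs_class_override(products_db):
    with pytest.raises(UnknownProductError):
        products_db.lookup("imaginarycide")
    assert products_db.lookup("imaginarycide", moa_class="suffocating").deposit == 4.72


def test_trial_ingredients_all_resolvable(products_db):
    from citrusvol import load_fixture

    for name in load_fixture("T5")["ingredient"].unique():
        assert products_db.lookup(name).deposit > 0


def test_cultivar_lookup(cultivars_db):
    assert cultivars_db.lookup("Clemenules").value == "medium"
    assert cultivars_db.lookup("owari").value == "low"
    assert cultivars_db.lookup("high").value == "high"  # explicit group passes through


def test_target_database_roundtrip(tmp_path, targets_db):
    """Serializing and reloading the target database reproduces it exactly."""
    out = tmp_path / "targets.yaml"
    payload = {
        "targets": [
            {
                "name": t.name,
                "application_class": t.application_class.value,
                "warnings": t.warnings,
            }
            for t in targets_db.targets.values()
        ]
    }
    out.write_text(yaml.safe_dump(payload))
    reloaded = TargetDatabase.load(out)
    assert {t.name: (t.application_class, tuple(t.warnings))
            for t in reloaded.targets.values()} == {
        t.name: (t.application_class, tuple(t.warnings))
        for t in targets_db.targets.values()
    }


def test_lad_database_roundtrip(tmp_path, lad_db):
    out = tmp_path / "lad.csv"
    lad_db.to_frame().to_csv(out, index=False)
    assert LadDatabase.load(out).to_frame().equals(lad_db.to_frame())
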