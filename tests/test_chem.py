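"""Elemental-composition arithmetic: masses, ppm deviations, RDB, enumeration."""

import itertools

import pytest

from adductomics.chem import (
    DEOXYRIBOSE_LOSS,
    MONOISOTOPIC_MASS,
    PROTON_MASS,
    ElementalComposition,
    EnumerationConstraints,
    enumerate_compositions,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
    rdb,
)
from adductomics.panels import reference_panel


def test_deoxyribose_neutral_loss_mass():
    """The deoxyribose moiety C5H8O3 weighs 116.0473 Da, the neutral-loss
    signature of protonated 2'-deoxyribonucleosides."""
    assert round(monoisotopic_mass("C5H8O3"), 4) == pytest.approx(DEOXYRIBOSE_LOSS)


@pytest.mark.parametrize(
    "formula,observed,expected_ppm",
    [
        ("C22H44O12N2", 529.2973, 1.1),
        ("C20H34O8N4", 459.2450, 0.1),
        ("C21H31O8N5", 482.2248, 0.5),
        ("C20H33O5N8", 466.2640, -1.4),
    ],
)
def test_mass_accuracy_of_panel_compositions(formula, observed, expected_ppm):
    """Observed precursor m/z of the panel adducts deviates from the
    protonated neutral composition by the catalogued ppm values."""
    theo = monoisotopic_mass(formula, "protonated")
    assert round(ppm_error(observed, theo), 1) == pytest.approx(expected_ppm)


@pytest.mark.parametrize(
    "formula,expected",
    [
        ("C22H44O12N2", 2.0),
        ("C21H31O8N5", 9.0),
        ("C20H33O5N8", 8.5),
        ("C20H34O8N4", 6.0),
        ("CH4", 0.0),
    ],
)
def test_rings_plus_double_bonds(formula, expected):
    assert rdb(formula) == pytest.approx(expected)


def test_ppm_error_identity_and_sign():
    assert ppm_error(500.0, 500.0) == 0.0
    assert ppm_error(500.0025, 500.0) == pytest.approx(5.0)
    with pytest.raises(ValueError):
        ppm_error(500.0, 0.0)


def test_mass_additivity():
    """Monoisotopic mass is additive over disjoint element sets."""
    a = parse_formula("C5H8")
    b = parse_formula("N2O3")
    ab = parse_formula("C5H8N2O3")
    assert monoisotopic_mass(ab) == pytest.approx(
        monoisotopic_mass(a) + monoisotopic_mass(b), abs=1e-9
    )


def test_composition_validation():
    with pytest.raises(ValueError):
        ElementalComposition({})
    with pytest.raises(ValueError):
        ElementalComposition({"Xx": 2})
    with pytest.raises(ValueError):
        parse_formula("notaformula!")


def test_hill_notation_round_trip():
    assert parse_formula("C22 H44 O12 N2").hill() == "C22H44N2O12"
    assert parse_formula("CH4").hill() == "CH4"


def test_protonation_adds_one_proton():
    comp = parse_formula("C10H13N5O4")  # 2'-deoxyguanosine
    assert monoisotopic_mass(comp, "protonated") - monoisotopic_mass(comp) == pytest.approx(
        PROTON_MASS
    )
    assert round(monoisotopic_mass(comp, "protonated"), 4) == pytest.approx(268.1040)


def test_enumeration_finds_generating_composition():
    res = enumerate_compositions(529.2973)
    formulas = [r.composition.hill() for r in res]
    assert "C22H44N2O12" in formulas
    top = res[0]
    assert abs(top.delta_ppm) <= 5.0 and top.rdb >= 0


def test_enumeration_infeasible_target_is_empty():
    # minimum reachable mass under min C9/O3/N2 far exceeds 50 Da
    assert enumerate_compositions(50.0) == []


def _brute_force(target_mz: float, c: EnumerationConstraints) -> set[str]:
    """Exhaustive quadruple loop over the full constraint grid."""
    out = set()
    for nc, nh, nn, no in itertools.product(
        range(c.min_c, c.max_c + 1),
        range(c.min_h, c.max_h + 1),
        range(c.min_n, c.max_n + 1),
        range(c.min_o, c.max_o + 1),
    ):
        mass = (
            nc * MONOISOTOPIC_MASS["C"]
            + nh * MONOISOTOPIC_MASS["H"]
            + nn * MONOISOTOPIC_MASS["N"]
            + no * MONOISOTOPIC_MASS["O"]
        )
        theo = mass + PROTON_MASS
        if abs(theo - target_mz) > c.ppm_tol * 1e-6 * target_mz:
            continue
        r = nc - nh / 2 + nn / 2 + 1
        if r < 0 or (c.require_integer_rdb and abs(r - round(r)) > 1e-9):
            continue
        out.add(ElementalComposition({"C": nc, "H": nh, "N": nn, "O": no}).hill())
    return out


@pytest.mark.parametrize("target", [300.1197, 286.1040, 330.1302])
def test_enumeration_matches_brute_force_on_bounded_grid(target):
    """The direct-solve search returns exactly the compositions a full
    exhaustive enumeration finds on a small grid."""
    c = EnumerationConstraints(max_c=12, max_h=20, max_n=6, max_o=6, ppm_tol=10.0)
    fast = {r.composition.hill() for r in enumerate_compositions(target, c)}
    assert fast == _brute_force(target, c)


def test_enumeration_ranked_by_abs_ppm():
    res = enumerate_compositions(529.2973, EnumerationConstraints(ppm_tol=20.0))
    devs = [abs(r.delta_ppm) for r in res]
    assert devs == sorted(devs)


def test_neutral_loss_pairs_pass_precursor_referenced_tolerance():
    """Every precursor/product pair of the reference panel satisfies the
    116.0473 Da loss within 5 ppm referenced to the precursor m/z, while at
    least one pair fails if the tolerance is referenced to the 116 Da loss
    itself — fixing the convention the screen uses."""
    panel = reference_panel()
    loss_err = panel.precursor_mz - panel.product_mz - DEOXYRIBOSE_LOSS
    ppm_precursor = loss_err / panel.precursor_mz * 1e6
    ppm_loss_scale = loss_err / DEOXYRIBOSE_LOSS * 1e6
    assert (ppm_precursor.abs() <= 5.0).all()
    assert (ppm_loss_scale.abs() > 5.0).any()
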