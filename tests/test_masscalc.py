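"""Mass chemistry: parsing, masses, tags, charges, fragments, ID filters."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from specprofiler import (
    AMINO_ACIDS,
    DEFAULT_CONSTANTS,
    IdentificationResult,
    Peptide,
    accept_identification,
    count_tags,
    format_peptide,
    fragment_ladder,
    labeled_mz,
    monoisotopic_mass,
    parse_peptide,
    ppm_error,
    predict_charge,
    residue_mass,
)

C = DEFAULT_CONSTANTS


def peptides(min_size=2, max_size=25):
    """Random peptides with optional acetylation and Met oxidations."""

    @st.composite
    def build(draw):
        seq = draw(st.text(alphabet=AMINO_ACIDS, min_size=min_size,
                           max_size=max_size))
        n_term = draw(st.sampled_from(["free", "acetyl"]))
        met_pos = [i + 1 for i, aa in enumerate(seq) if aa == "M"]
        mods = tuple(
            (p, "oxidation")
            for p in met_pos
            if draw(st.booleans())
        )
        return Peptide(seq, n_term=n_term, mods=mods)

    return build()


# ---------------------------------------------------------------------------
# parsing

@pytest.mark.parametrize("text, seq, n_term, mods", [
    ("Ac-ADEIAKAQVAR", "ADEIAKAQVAR", "acetyl", ()),
    ("SAMoxTEEAAVAIKAMAK", "SAMTEEAAVAIKAMAK", "free", ((3, "oxidation"),)),
    ("IIEPSLR", "IIEPSLR", "free", ()),
])
def test_parse_peptide(text, seq, n_term, mods):
    p = parse_peptide(text)
    assert (p.sequence, p.n_term, p.mods) == (seq, n_term, mods)
    assert format_peptide(p) == text


@pytest.mark.parametrize("bad", ["", "AXB", "AoxB", "Ac-", "PEPT1DE"])
def test_parse_peptide_rejects(bad):
    with pytest.raises(ValueError):
        parse_peptide(bad)


@given(peptides())
@settings(max_examples=200, deadline=None)
def test_parse_format_roundtrip(p):
    assert parse_peptide(format_peptide(p)) == p


# ---------------------------------------------------------------------------
# monoisotopic mass

PRINTED_MASSES = [
    ("Ac-ADEIAKAQVAR", 1212.65),
    ("SAMoxTEEAAVAIKAMAK", 1636.82),
    ("AELEQLKGQGKSR", 1442.78),
    ("Ac-TTTTTFKGVDPNSRNSSR", 2009.98),
    ("NMDVPNIKR", 1085.57),
    ("IIEPSLR", 826.49),
    ("AVGSGSKGKGGEIQPVSV", 1655.89),
    ("ADKVPKTAENF", 1218.62),
    ("EKTPKTPKGPSSVEDIKA", 1911.03),
    ("VFDVELL", 833.45),
    ("ALEQATR", 787.42),
    ("AVKQFEESQGR", 1277.64),
    ("KVPQVSTPTLVEVSR", 1638.93),
    ("KQTALVELLK", 1141.71),
    ("LPESK", 572.32),
    ("GQEFTITGQK", 1107.56),
]


@pytest.mark.parametrize("text, expected", PRINTED_MASSES)
def test_monoisotopic_mass_reference_values(text, expected):
    calc = monoisotopic_mass(parse_peptide(text))
    assert abs(ppm_error(calc, expected)) <= 10


def test_monoisotopic_mass_single_glycine():
    assert monoisotopic_mass(Peptide("G")) == pytest.approx(75.0320, abs=1e-3)


@given(peptides())
@settings(max_examples=200, deadline=None)
def test_mass_additivity_under_cterm_cleavage(p):
    """Removing the C-terminal residue removes exactly its residue mass."""
    truncated = p.drop_cterm()
    lost = monoisotopic_mass(p) - monoisotopic_mass(truncated)
    mod_on_last = sum(1 for pos, _ in p.mods if pos == len(p.sequence))
    expected = residue_mass(p.sequence[-1]) + mod_on_last * C.oxidation_delta
    assert lost == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# tags and charge

@pytest.mark.parametrize("text, t", [
    ("EKTPKTPKGPSSVEDIKA", 5),
    ("Ac-TTTTTFKGVDPNSRNSSR", 1),
    ("VFDVELL", 1),
])
def test_count_tags(text, t):
    assert count_tags(parse_peptide(text)) == t


@pytest.mark.parametrize("text, z", [
    ("AELEQLKGQGKSR", 4),
    ("Ac-ADEIAKAQVAR", 2),
    ("VFDVELL", 1),
])
def test_predict_charge(text, z):
    assert predict_charge(parse_peptide(text)) == z


@given(peptides(min_size=1))
@settings(max_examples=200, deadline=None)
def test_tags_never_exceed_charge(p):
    assert count_tags(p) <= predict_charge(p)


# ---------------------------------------------------------------------------
# labeled m/z

def test_labeled_mz_reference_value():
    assert labeled_mz(parse_peptide("IIEPSLR"), "D0", 2) == pytest.approx(
        477.803, abs=1e-3)


def test_label_mass_steps():
    p = parse_peptide("AVFDK")  # T = 2 (Lys + free N-terminus)
    assert count_tags(p) == 2
    z = predict_charge(p)
    d3 = labeled_mz(p, "D3", z) - labeled_mz(p, "D0", z)
    d12 = labeled_mz(p, "D12", z) - labeled_mz(p, "D9", z)
    # per tag: 3 deuteriums (3.01883 Da) and 3 13C (3.01007 Da)
    assert d3 * z / 2 == pytest.approx(3.01883, abs=1e-4)
    assert d12 * z / 2 == pytest.approx(3.01007, abs=1e-4)


def test_labeled_mz_rejects_charge_below_tags():
    p = parse_peptide("AKAKAK")  # T = 4
    with pytest.raises(ValueError):
        labeled_mz(p, "D0", 2)


# ---------------------------------------------------------------------------
# ppm

def test_ppm_error():
    assert ppm_error(826.49, 826.49) == 0
    assert ppm_error(1000.01, 1000.00) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        ppm_error(1.0, 0.0)


# ---------------------------------------------------------------------------
# fragment ladders

def test_fragment_ladder_reference_ions():
    b, y = fragment_ladder(parse_peptide("IIEPSLR"))
    assert y[0] == pytest.approx(175.119, abs=1e-3)  # y1 of a ...R peptide
    assert b[1] == pytest.approx(227.175, abs=1e-3)  # b2 = 2 x Ile + proton


def test_fragment_ladder_rejects_single_residue():
    with pytest.raises(ValueError):
        fragment_ladder(Peptide("G"))


@given(peptides())
@settings(max_examples=1000, deadline=None)
def test_by_complementarity(p):
    """b_i + y_{n-i} = neutral mass + 2 protons, for every i."""
    b, y = fragment_ladder(p)
    total = monoisotopic_mass(p) + 2 * C.proton
    n = len(p.sequence)
    for i in range(n - 1):
        assert b[i] + y[n - 2 - i] == pytest.approx(total, abs=1e-9)


# ---------------------------------------------------------------------------
# identification acceptance

def test_accept_identification_all_criteria_met():
    p = parse_peptide("IIEPSLR")
    b, y = fragment_ladder(p)
    res = accept_identification(
        p, monoisotopic_mass(p), predict_charge(p), b[:5] + y[:5],
        tags_observed=count_tags(p))
    assert res.accepted and res.failed == ()


def test_accept_identification_parent_mass_off():
    p = parse_peptide("IIEPSLR")
    b, y = fragment_ladder(p)
    mass = monoisotopic_mass(p) * (1 + 60e-6)  # 60 ppm off
    res = accept_identification(p, mass, predict_charge(p), b + y,
                                tags_observed=count_tags(p))
    assert not res.accepted and "parent_mass" in res.failed


def test_accept_identification_fragment_fraction():
    p = parse_peptide("IIEPSLR")
    b, y = fragment_ladder(p)
    frags = (b + y)[:7] + [999.0, 1999.0, 2999.0]  # 7 of 10 match
    res = accept_identification(p, monoisotopic_mass(p), predict_charge(p),
                                frags, tags_observed=count_tags(p))
    assert not res.accepted
    assert res.failed == ("fragment_fraction",)
    assert res.fragment_fraction == pytest.approx(0.7)


def test_accept_identification_wrong_charge_and_tags():
    p = parse_peptide("IIEPSLR")
    b, y = fragment_ladder(p)
    res = accept_identification(p, monoisotopic_mass(p),
                                predict_charge(p) + 1, b + y,
                                tags_observed=count_tags(p) + 1)
    assert set(res.failed) == {"charge", "tag_count"}


def test_accept_identification_empty_fragments_rejects_without_raising():
    p = parse_peptide("IIEPSLR")
    res = accept_identification(p, monoisotopic_mass(p), predict_charge(p),
                                [], tags_observed=count_tags(p))
    assert isinstance(res, IdentificationResult)
    assert not res.accepted and "fragment_fraction" in res.failed
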