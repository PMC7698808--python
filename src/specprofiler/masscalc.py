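"""Peptide mass chemistry for TMAB-multiplex peptidomics.

Peptides are plain one-letter sequences with an optional N-terminal acetyl
group and optional methionine oxidations, written in the compact dialect
used throughout the CPZ substrate screens: ``Ac-ADEIAKAQVAR``,
``SAMoxTEEAAVAIKAMAK``.  This module computes neutral monoisotopic masses,
TMAB-labeled m/z values, b/y fragment ladders, and applies the
identification-acceptance filters (parent mass ppm, expected charge,
tag count, fragment-match fraction).

TMAB (4-trimethylammoniumbutyrate) tags react with free amines — the
alpha-amine when the N-terminus is unmodified, and every lysine side chain —
and each tag carries one fixed positive charge.  Isotopic variants D0, D3,
D6, D9 differ by three deuteriums each; D12 adds three 13C atoms on top
of D9.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from pyteomics import mass as _pmass

__all__ = [
    "AMINO_ACIDS",
    "LABELS",
    "MassConstants",
    "Peptide",
    "LabeledForm",
    "DEFAULT_CONSTANTS",
    "parse_peptide",
    "format_peptide",
    "monoisotopic_mass",
    "residue_mass",
    "count_tags",
    "predict_charge",
    "labeled_mz",
    "ppm_error",
    "fragment_ladder",
    "accept_identification",
    "IdentificationResult",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: TMAB label channels, ordered by increasing tag mass.
LABELS = ("D0", "D3", "D6", "D9", "D12")

# Mass differences between heavy and light isotopes (Da).
_DEUTERIUM_STEP = 1.00627674590  # 2H - 1H
_C13_STEP = 1.00335483507  # 13C - 12C

_PROTON = 1.00727646688
_WATER = 18.0105646863
_ACETYL = 42.0105646863
_OXIDATION = 15.9949146221
_TMAB_D0 = 128.1075  # trimethylammonium-butyryl, fixed +1 charge


def _default_tag_masses() -> dict[str, float]:
    d0 = _TMAB_D0
    return {
        "D0": d0,
        "D3": d0 + 3 * _DEUTERIUM_STEP,
        "D6": d0 + 6 * _DEUTERIUM_STEP,
        "D9": d0 + 9 * _DEUTERIUM_STEP,
        "D12": d0 + 9 * _DEUTERIUM_STEP + 3 * _C13_STEP,
    }


@dataclass(frozen=True)
class MassConstants:
    """Monoisotopic mass constants.

    Residue masses default to the standard values shipped with pyteomics;
    every constant can be overridden, e.g. from a config file, for
    non-standard chemistries.
    """

    residue_masses: Mapping[str, float] = field(
        default_factory=lambda: {aa: _pmass.std_aa_mass[aa] for aa in AMINO_ACIDS}
    )
    water: float = _WATER
    proton: float = _PROTON
    acetyl_delta: float = _ACETYL
    oxidation_delta: float = _OXIDATION
    tag_mass: Mapping[str, float] = field(default_factory=_default_tag_masses)

    def __post_init__(self) -> None:
        masses = [self.tag_mass[l] for l in LABELS if l in self.tag_mass]
        if any(b <= a for a, b in zip(masses, masses[1:])):
            raise ValueError("tag masses must be strictly increasing D0 -> D12")


DEFAULT_CONSTANTS = MassConstants()


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence with N-terminal state and residue modifications.

    ``mods`` holds ``(position, name)`` pairs with 1-based positions;
    the only supported modification is methionine oxidation.  N-terminal
    acetylation is a property of the terminus, not a positional mod.
    """

    sequence: str
    n_term: str = "free"  # "free" | "acetyl"
    mods: tuple[tuple[int, str], ...] = ()
    precursor_name: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"unknown residue letter(s): {sorted(bad)}")
        if self.n_term not in ("free", "acetyl"):
            raise ValueError(f"invalid n_term state: {self.n_term!r}")
        for pos, name in self.mods:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"mod position {pos} outside sequence")
            if name != "oxidation":
                raise ValueError(f"unsupported modification: {name!r}")
            if self.sequence[pos - 1] != "M":
                raise ValueError(
                    f"oxidation at position {pos} ({self.sequence[pos - 1]}): "
                    "only Met may be oxidized"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return format_peptide(self)

    def drop_cterm(self) -> "Peptide":
        """The peptide minus its C-terminal residue (mods there removed)."""
        if len(self.sequence) < 2:
            raise ValueError("cannot truncate a single-residue peptide")
        n = len(self.sequence) - 1
        return Peptide(
            self.sequence[:n],
            n_term=self.n_term,
            mods=tuple((p, m) for p, m in self.mods if p <= n),
            precursor_name=self.precursor_name,
        )


@dataclass(frozen=True)
class LabeledForm:
    """One TMAB-labeled, charged form of a peptide as it appears in MS1."""

    peptide: Peptide
    label: str
    n_tags: int
    charge: int
    mz: float

    def __post_init__(self) -> None:
        if self.n_tags < 0 or self.charge < 1 or self.n_tags > self.charge:
            raise ValueError("require 0 <= n_tags <= charge and charge >= 1")


_PEPTIDE_RE = re.compile(r"^(Ac-)?([A-Za-z]+)$")


def parse_peptide(text: str, precursor_name: str | None = None) -> Peptide:
    """Parse the compact modification dialect into a :class:`Peptide`.

    ``Ac-`` prefix marks N-terminal acetylation; a lowercase ``ox``
    immediately after a residue letter marks oxidation of that residue
    (Met only).  Round-trips exactly through :func:`format_peptide`.
    """
    m = _PEPTIDE_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse peptide string: {text!r}")
    n_term = "acetyl" if m.group(1) else "free"
    body = m.group(2)
    sequence = []
    mods = []
    i = 0
    while i < len(body):
        c = body[i]
        if body[i : i + 2] == "ox":
            if not sequence:
                raise ValueError(f"'ox' before any residue in {text!r}")
            if sequence[-1] != "M":
                raise ValueError(
                    f"'ox' after non-Met residue {sequence[-1]!r} in {text!r}"
                )
            mods.append((len(sequence), "oxidation"))
            i += 2
            continue
        if c not in AMINO_ACIDS:
            raise ValueError(f"unknown residue letter {c!r} in {text!r}")
        sequence.append(c)
        i += 1
    return Peptide("".join(sequence), n_term, tuple(mods), precursor_name)


def format_peptide(p: Peptide) -> str:
    """Inverse of :func:`parse_peptide`."""
    mod_at = {pos for pos, _ in p.mods}
    out = ["Ac-"] if p.n_term == "acetyl" else []
    for i, aa in enumerate(p.sequence, start=1):
        out.append(aa)
        if i in mod_at:
            out.append("ox")
    return "".join(out)


def residue_mass(aa: str, constants: MassConstants = DEFAULT_CONSTANTS) -> float:
    """Monoisotopic residue (dehydrated) mass of a one-letter amino acid."""
    try:
        return constants.residue_masses[aa]
    except KeyError:
        raise ValueError(f"unknown residue {aa!r}") from None


def monoisotopic_mass(p: Peptide, constants: MassConstants = DEFAULT_CONSTANTS) -> float:
    """Neutral, unlabeled monoisotopic mass (Da).

    Sum of residue masses plus one water, plus the acetyl and oxidation
    deltas where present.  This is the "Theor M" quantity of the substrate
    tables: TMAB tags are excluded by convention.
    """
    m = sum(constants.residue_masses[aa] for aa in p.sequence) + constants.water
    if p.n_term == "acetyl":
        m += constants.acetyl_delta
    m += constants.oxidation_delta * len(p.mods)
    return m


def count_tags(p: Peptide) -> int:
    """Number of TMAB tags the peptide incorporates (T).

    One per free amine: every Lys side chain, plus the alpha-amine unless
    the N-terminus is acetylated.  Tags on Tyr hydroxyls are removed by
    hydroxylamine treatment during sample prep and never counted.
    """
    return p.sequence.count("K") + (1 if p.n_term == "free" else 0)


def predict_charge(p: Peptide) -> int:
    """Expected positive charge (Z): basic residues plus the free N-terminus."""
    basics = sum(p.sequence.count(aa) for aa in "RKH")
    return basics + (1 if p.n_term == "free" else 0)


def labeled_mz(
    p: Peptide,
    label: str,
    charge: int,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> float:
    """m/z of the TMAB-labeled peptide at a given charge.

    Each tag carries one fixed positive charge, so only ``charge - T``
    protons are added.
    """
    t = count_tags(p)
    if charge < t:
        raise ValueError(f"charge {charge} < tag count {t} for {format_peptide(p)}")
    if label not in constants.tag_mass:
        raise ValueError(f"unknown label {label!r}")
    neutral = monoisotopic_mass(p, constants)
    return (neutral + t * constants.tag_mass[label] + (charge - t) * constants.proton) / charge


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return (observed - theoretical) / theoretical * 1e6


def fragment_ladder(
    p: Peptide, constants: MassConstants = DEFAULT_CONSTANTS
) -> tuple[list[float], list[float]]:
    """Singly-protonated b- and y-ion ladders.

    Returns ``(b, y)`` with ``n-1`` ions each for a length-``n`` peptide.
    b-ions include the N-terminal acetyl mass where present; oxidation
    masses ride with the residue that carries them.  Complementarity
    ``b_i + y_{n-i} == neutral + 2*proton`` holds exactly.
    """
    n = len(p.sequence)
    if n < 2:
        raise ValueError("fragment ladder needs at least two residues")
    mod_at = dict()
    for pos, _ in p.mods:
        mod_at[pos] = mod_at.get(pos, 0.0) + constants.oxidation_delta
    res = [
        constants.residue_masses[aa] + mod_at.get(i, 0.0)
        for i, aa in enumerate(p.sequence, start=1)
    ]
    nterm = constants.acetyl_delta if p.n_term == "acetyl" else 0.0

    b = []
    acc = nterm
    for r in res[:-1]:
        acc += r
        b.append(acc + constants.proton)
    y = []
    acc = constants.water
    for r in reversed(res[1:]):
        acc += r
        y.append(acc + constants.proton)
    return b, y


@dataclass(frozen=True)
class IdentificationResult:
    accepted: bool
    failed: tuple[str, ...]  # criteria that failed, in check order
    ppm: float
    fragment_fraction: float

    def __bool__(self) -> bool:
        return self.accepted


def accept_identification(
    candidate: Peptide,
    parent_mass: float,
    parent_charge: int,
    observed_fragments: Sequence[float],
    tags_observed: int,
    tol_ppm: float = 50.0,
    min_match: float = 0.8,
    fragment_tol_da: float = 0.02,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> IdentificationResult:
    """Apply the identification-acceptance filters to a candidate match.

    Accept iff the parent mass is within ``tol_ppm`` of theoretical, the
    charge equals the basic-residues-plus-N-terminus expectation, the tag
    count is correct, and at least ``min_match`` of the observed fragments
    match a predicted b/y ion within ``fragment_tol_da``.  An empty
    fragment list is a rejection (no evidence), never an exception.
    """
    failed = []
    err = ppm_error(parent_mass, monoisotopic_mass(candidate, constants))
    if abs(err) > tol_ppm:
        failed.append("parent_mass")
    if parent_charge != predict_charge(candidate):
        failed.append("charge")
    if tags_observed != count_tags(candidate):
        failed.append("tag_count")
    if observed_fragments and len(candidate) >= 2:
        b, y = fragment_ladder(candidate, constants)
        ladder = sorted(b + y)
        hits = sum(
            1
            for f in observed_fragments
            if min(abs(f - m) for m in ladder) <= fragment_tol_da
        )
        frac = hits / len(observed_fragments)
    else:
        frac = 0.0
    if frac < min_match:
        failed.append("fragment_fraction")
    return IdentificationResult(not failed, tuple(failed), err, frac)
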