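"""Substrate/product classification and product-to-precursor linking.

Classification applies fixed intensity-ratio thresholds at the highest
enzyme concentration: a decrease of at least 60% marks a good substrate,
20-60% a weak substrate; peptides whose max-concentration channel is
unchanged but whose intensity rises above 120% of the no-enzyme control
at one or more concentrations are products of the enzyme.  A product
peptide is linked back to its precursor — the library peptide exceeding
it by exactly one C-terminal residue — which recovers the cleaved residue
(P1') and the cleavage-site context (P1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .masscalc import (
    DEFAULT_CONSTANTS,
    MassConstants,
    Peptide,
    monoisotopic_mass,
)
from .peakgroups import ExperimentDesign, RatioRecord

__all__ = [
    "CLASSES",
    "CleavageEvent",
    "AmbiguousPrecursorError",
    "classify_record",
    "link_product",
    "link_product_by_mass",
]

CLASSES = ("good_substrate", "weak_substrate", "non_substrate", "product",
           "unclassified")


@dataclass(frozen=True)
class CleavageEvent:
    """A single carboxypeptidase cleavage: precursor -> product + residue."""

    precursor: Peptide
    product: Peptide
    cleaved_aa: str

    def __post_init__(self) -> None:
        if self.product.sequence + self.cleaved_aa != self.precursor.sequence:
            raise ValueError("product + cleaved residue must equal precursor")

    @property
    def p1_prime(self) -> str:
        """The residue removed (C-terminal residue of the precursor)."""
        return self.cleaved_aa

    @property
    def p1(self) -> str:
        """The penultimate residue of the precursor."""
        return self.precursor.sequence[-2]


class AmbiguousPrecursorError(ValueError):
    def __init__(self, product: Peptide, candidates: Sequence[Peptide]):
        self.product = product
        self.candidates = list(candidates)
        super().__init__(
            f"product {product.sequence}: multiple precursor candidates "
            f"{[c.sequence for c in self.candidates]}"
        )


def classify_record(
    r: RatioRecord,
    design: ExperimentDesign | None = None,
    good_cut: float = 0.60,
    weak_cut: float = 0.20,
    product_cut: float = 1.20,
) -> str:
    """Classify a ratio record; also sets ``r.classification`` and flags.

    The substrate decision is made on the highest-concentration channel
    present; the product rule (any ratio above ``product_cut``) applies
    only when that channel shows no substrate-level decrease, so a clear
    depletion at the top dose is never re-labeled a product because of a
    noisy low-dose overshoot.  Records without any non-control ratio are
    ``unclassified``.

    A diagnostic flag ``no_partial_decrease_at_10nM`` is attached to good
    substrates whose 10 nM channel (when present) shows no decrease at
    all; it never changes the class.
    """
    if not r.ratios:
        r.classification = "unclassified"
        return r.classification
    top = max(r.ratios)
    decrease = 1.0 - r.ratios[top]
    if decrease >= good_cut:
        cls = "good_substrate"
    elif decrease >= weak_cut:
        cls = "weak_substrate"
    elif any(v > product_cut for v in r.ratios.values()):
        cls = "product"
    else:
        cls = "non_substrate"
    flags = []
    if cls == "good_substrate" and 10.0 in r.ratios and r.ratios[10.0] >= 1.0:
        flags.append("no_partial_decrease_at_10nM")
    r.classification = cls
    r.flags = tuple(flags)
    return cls


def link_product(
    product: Peptide,
    library: Iterable[Peptide],
    allowed_cleaved: Iterable[str] | None = None,
) -> CleavageEvent | None:
    """Find the precursor of a product peptide by sequence extension.

    The precursor must be a library peptide equal to the product plus one
    C-terminal residue (drawn from ``allowed_cleaved``, default all 20).
    Multiple distinct matches raise :class:`AmbiguousPrecursorError`;
    no match returns ``None``.
    """
    allowed = set(allowed_cleaved) if allowed_cleaved is not None else None
    hits: dict[str, Peptide] = {}
    for cand in library:
        if len(cand.sequence) != len(product.sequence) + 1:
            continue
        if not cand.sequence.startswith(product.sequence):
            continue
        if cand.n_term != product.n_term:
            continue
        aa = cand.sequence[-1]
        if allowed is not None and aa not in allowed:
            continue
        hits[cand.sequence] = cand
    if not hits:
        return None
    if len(hits) > 1:
        raise AmbiguousPrecursorError(product, list(hits.values()))
    precursor = next(iter(hits.values()))
    return CleavageEvent(precursor, product, precursor.sequence[-1])


def link_product_by_mass(
    product_mass: float,
    precursor_mass: float,
    tol_da: float = 0.01,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> str | None:
    """Infer the cleaved residue from a precursor/product mass difference.

    Cleavage removes exactly one residue mass (the product keeps the
    water), so the difference identifies the residue within ``tol_da``.
    Returns the one-letter code, or ``None`` if nothing matches.
    Leu/Ile are isobaric; 'L' is returned by convention.
    """
    diff = precursor_mass - product_mass
    best = None
    for aa, m in constants.residue_masses.items():
        if aa == "I":  # isobaric with Leu; report L
            continue
        d = abs(diff - m)
        if d <= tol_da and (best is None or d < best[1]):
            best = (aa, d)
    return best[0] if best else None
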