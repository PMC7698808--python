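"""Positional residue-frequency profiles at the cleavage site.

Carboxypeptidases remove the C-terminal residue, so in Schechter-Berger
nomenclature the C-terminal residue of a substrate occupies P1' (it ends
up on the prime side of the scissile bond) and the penultimate residue
occupies P1.  Profiles tally residue occurrences at one of these positions
per classification class; the P1 analysis is usually restricted to
peptides whose P1' residue is permissive (Arg/Lys for CPZ), so that P1
preferences are read off substrates the enzyme could actually engage.

Frequencies are raw per-class fractions; the enrichment ratio against the
non-substrate background is a descriptive convenience, not an inferential
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .masscalc import AMINO_ACIDS, Peptide
from .peakgroups import RatioRecord

__all__ = [
    "PERMISSIVE_P1_PRIME",
    "SpecificityProfile",
    "cterm_context",
    "build_profile",
    "preference_summary",
]

#: Residues CPZ accepts at P1' (the cleaved position).
PERMISSIVE_P1_PRIME = frozenset({"R", "K"})

_SUBSTRATE_CLASSES = ("good_substrate", "weak_substrate")


@dataclass
class SpecificityProfile:
    """Residue counts and frequencies at one position, per class."""

    position: str  # "p1_prime" | "p1"
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    n_per_class: dict[str, int] = field(default_factory=dict)

    @property
    def frequencies(self) -> dict[str, dict[str, float]]:
        out = {}
        for cls, tab in self.counts.items():
            n = self.n_per_class.get(cls, 0)
            out[cls] = {aa: (c / n if n else 0.0) for aa, c in tab.items()}
        return out

    def to_frame(self) -> pd.DataFrame:
        """Class x residue count matrix (all 20 residues, zeros explicit)."""
        return pd.DataFrame(self.counts).T.reindex(columns=list(AMINO_ACIDS),
                                                   fill_value=0).fillna(0).astype(int)


def cterm_context(p: Peptide) -> tuple[str, str]:
    """(P1' residue, P1 residue) of a peptide read as a cleavage substrate."""
    if len(p.sequence) < 2:
        raise ValueError("need at least two residues for a P1'/P1 context")
    return p.sequence[-1], p.sequence[-2]


def build_profile(
    records: Iterable[RatioRecord],
    position: str = "p1_prime",
    restrict_p1prime: Iterable[str] | None = None,
    classes: Sequence[str] | None = None,
) -> SpecificityProfile:
    """Tally residues at P1' or P1 for each classification class.

    ``restrict_p1prime`` (used for P1 analysis) drops records whose P1'
    residue falls outside the set before tallying.  Empty input yields an
    all-zero profile.  Residues never observed keep explicit zero counts
    so profiles are comparable across experiments.
    """
    if position not in ("p1_prime", "p1"):
        raise ValueError(f"unknown position {position!r}")
    restrict = set(restrict_p1prime) if restrict_p1prime is not None else None
    prof = SpecificityProfile(position=position)
    wanted = set(classes) if classes is not None else None
    for r in records:
        if r.peptide is None or len(r.peptide.sequence) < 2:
            continue
        cls = r.classification
        if wanted is not None and cls not in wanted:
            continue
        p1p, p1 = cterm_context(r.peptide)
        if restrict is not None and p1p not in restrict:
            continue
        aa = p1p if position == "p1_prime" else p1
        tab = prof.counts.setdefault(cls, {a: 0 for a in AMINO_ACIDS})
        tab[aa] += 1
        prof.n_per_class[cls] = prof.n_per_class.get(cls, 0) + 1
    return prof


def preference_summary(
    profile: SpecificityProfile,
    substrate_classes: Sequence[str] = _SUBSTRATE_CLASSES,
    background_class: str = "non_substrate",
) -> pd.DataFrame:
    """Rank residues by pooled substrate frequency with background enrichment.

    Enrichment is substrate frequency / non-substrate frequency; a residue
    absent from the background gets ``inf`` and an ``undefined_background``
    flag rather than an error.  Residues never seen among substrates are
    omitted.
    """
    sub_counts = {a: 0 for a in AMINO_ACIDS}
    n_sub = 0
    for cls in substrate_classes:
        for aa, c in profile.counts.get(cls, {}).items():
            sub_counts[aa] += c
        n_sub += profile.n_per_class.get(cls, 0)
    bg = profile.frequencies.get(background_class, {a: 0.0 for a in AMINO_ACIDS})

    rows = []
    for aa, c in sub_counts.items():
        if c == 0:
            continue
        f = c / n_sub
        b = bg.get(aa, 0.0)
        rows.append({
            "residue": aa,
            "substrate_count": c,
            "substrate_frequency": f,
            "background_frequency": b,
            "enrichment": (f / b) if b > 0 else float("inf"),
            "undefined_background": b == 0,
        })
    df = pd.DataFrame(rows, columns=["residue", "substrate_count",
                                     "substrate_frequency",
                                     "background_frequency", "enrichment",
                                     "undefined_background"])
    if len(df):
        df = df.sort_values(["substrate_frequency", "residue"],
                            ascending=[False, True]).reset_index(drop=True)
    return df
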