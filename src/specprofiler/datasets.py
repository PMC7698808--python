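"""Bundled reference tables from the CPZ substrate screens.

Four small TSV fixtures ship with the package: the dansyl-substrate
kinetic constants and the three substrate/product tables of the HEK293T
and tryptic peptide-library screens.  Loaders return pandas DataFrames
("n.d." entries become NaN) and can re-derive :class:`RatioRecord`
objects from the printed ratio columns, so the classifier and profiler
can be run directly on the published numbers.

Two theoretical-mass entries (GQEFTITGQKR 1263.60 and LF 278.15 in the
tryptic table) are internally inconsistent with their own ppm columns;
``MASS_CHECK_EXCLUDE`` lists them so mass self-validation skips them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .masscalc import DEFAULT_CONSTANTS, MassConstants, monoisotopic_mass, parse_peptide, ppm_error
from .peakgroups import ExperimentDesign, RatioRecord

__all__ = [
    "MASS_CHECK_EXCLUDE",
    "load_kinetic_constants",
    "load_hek_substrates",
    "load_hek_products",
    "load_tryptic_table",
    "records_from_table",
    "validate_table_masses",
]

#: Sequences whose printed theoretical mass is a known typo.
MASS_CHECK_EXCLUDE = frozenset({"GQEFTITGQKR", "LF"})

_FILES = {
    "kinetics": "table1_kinetics.tsv",
    "hek_substrates": "table2_hek_substrates.tsv",
    "hek_products": "table3_hek_products.tsv",
    "tryptic": "table4_tryptic.tsv",
}


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("specprofiler.data").joinpath(_FILES[name])
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#", na_values=["n.d."])


def load_kinetic_constants() -> pd.DataFrame:
    return _load("kinetics")


def load_hek_substrates() -> pd.DataFrame:
    return _load("hek_substrates")


def load_hek_products() -> pd.DataFrame:
    return _load("hek_products")


def load_tryptic_table() -> pd.DataFrame:
    return _load("tryptic")


def records_from_table(df: pd.DataFrame) -> list[RatioRecord]:
    """Rebuild RatioRecords from a reference table's printed ratio columns."""
    ratio_cols = {
        float(c.removeprefix("ratio_").removesuffix("nM")): c
        for c in df.columns
        if c.startswith("ratio_")
    }
    out = []
    for _, row in df.iterrows():
        ratios = {
            conc: float(row[col])
            for conc, col in ratio_cols.items()
            if pd.notna(row[col])
        }
        out.append(RatioRecord(peptide=parse_peptide(row["sequence"]), ratios=ratios))
    return out


def validate_table_masses(
    df: pd.DataFrame,
    tol_ppm: float = 10.0,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Self-check: recompute theor_m for every row and report the ppm error.

    Rows listed in :data:`MASS_CHECK_EXCLUDE` are flagged but not required
    to pass.  Raises if any non-excluded row misses ``tol_ppm``.
    """
    rows = []
    for _, row in df.iterrows():
        p = parse_peptide(row["sequence"])
        calc = monoisotopic_mass(p, constants)
        err = ppm_error(calc, float(row["theor_m"]))
        rows.append({
            "sequence": row["sequence"],
            "printed": float(row["theor_m"]),
            "computed": calc,
            "ppm": err,
            "excluded": p.sequence in MASS_CHECK_EXCLUDE,
        })
    report = pd.DataFrame(rows)
    bad = report[(~report["excluded"]) & (report["ppm"].abs() > tol_ppm)]
    if len(bad):
        raise ValueError(
            "printed theoretical masses failed self-check:\n" + bad.to_string()
        )
    return report
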