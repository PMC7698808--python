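"""End-to-end pipeline: features -> peak sets -> ratios -> classes -> profiles.

A :class:`PipelineConfig` gathers every threshold the stages use (the
defaults are the screen's published values: 50 ppm parent tolerance, 80%
fragment match, 60%/20% substrate decreases, 1.20 product ratio) and a
single :func:`run_pipeline` call produces the ratio/classification report,
the P1' and P1 specificity profiles, and a structured log echoing every
threshold, deterministically for a given input, config and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .masscalc import (
    DEFAULT_CONSTANTS,
    MassConstants,
    Peptide,
    count_tags,
    format_peptide,
    labeled_mz,
    monoisotopic_mass,
    parse_peptide,
    predict_charge,
    ppm_error,
)
from .peakgroups import (
    ExperimentDesign,
    Feature,
    PeakSet,
    RatioRecord,
    compute_ratios,
    group_peaksets,
)
from .classify import classify_record, link_product, AmbiguousPrecursorError
from .specificity import PERMISSIVE_P1_PRIME, build_profile, preference_summary

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "identify_peakset"]

logger = logging.getLogger("specprofiler")


@dataclass
class PipelineConfig:
    """All tunables of the screen analysis in one declarative object."""

    design: ExperimentDesign = field(default_factory=ExperimentDesign.hek_screen)
    good_cut: float = 0.60
    weak_cut: float = 0.20
    product_cut: float = 1.20
    parent_tol_ppm: float = 50.0
    fragment_tol_da: float = 0.02
    min_fragment_match: float = 0.8
    mz_tol_ppm: float = 10.0
    rt_window_min: float = 0.5
    t_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    permissive_p1prime: frozenset[str] = PERMISSIVE_P1_PRIME
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "design" in raw:
            raw["design"] = ExperimentDesign(
                {k: float(v) for k, v in raw["design"]["channel_map"].items()},
                name=raw["design"].get("name", ""),
            )
        if "t_range" in raw:
            raw["t_range"] = tuple(raw["t_range"])
        if "permissive_p1prime" in raw:
            raw["permissive_p1prime"] = frozenset(raw["permissive_p1prime"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["design"] = {"channel_map": dict(self.design.channel_map),
                       "name": self.design.name}
        d["t_range"] = list(self.t_range)
        d["permissive_p1prime"] = sorted(self.permissive_p1prime)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class PipelineResult:
    report: pd.DataFrame  # one row per quantified peptide / peak set
    p1_prime_profile: pd.DataFrame  # class x residue counts
    p1_profile: pd.DataFrame
    preferences: pd.DataFrame
    records: list[RatioRecord]
    log: list[dict]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rep = self.report.copy()
        for c in rep.columns:
            if c.startswith("ratio_"):
                rep[c] = rep[c].map(
                    lambda v: "n.d." if pd.isna(v) else f"{v:.2f}")
        rep.to_csv(outdir / "classification.tsv", sep="\t", index=False)
        self.p1_prime_profile.to_csv(outdir / "profile_p1prime.tsv", sep="\t")
        self.p1_profile.to_csv(outdir / "profile_p1.tsv", sep="\t")
        self.preferences.to_csv(outdir / "preferences.tsv", sep="\t", index=False)
        pd.DataFrame(self.log).to_csv(outdir / "run_log.tsv", sep="\t", index=False)


def identify_peakset(
    ps: PeakSet,
    library: Sequence[Peptide],
    tol_ppm: float = 50.0,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> Peptide | None:
    """Match a peak set to a library peptide by labeled m/z, charge and tags.

    The candidate must reproduce the lowest observed channel's m/z within
    ``tol_ppm`` at the set's charge, carry the set's tag count, and have
    the expected charge — the same filters used to accept identifications.
    """
    label = next(iter(sorted(ps.channel_intensity,
                             key=lambda l: constants.tag_mass[l])))
    best = None
    for cand in library:
        if count_tags(cand) != ps.n_tags:
            continue
        if predict_charge(cand) != ps.charge:
            continue
        mz = labeled_mz(cand, label, ps.charge, constants)
        err = abs(ppm_error(ps.base_mz, mz))
        if err <= tol_ppm and (best is None or err < best[1]):
            best = (cand, err)
    return best[0] if best else None


def _report_frame(records: list[RatioRecord], design: ExperimentDesign,
                  events: Mapping[str, str]) -> pd.DataFrame:
    concs = sorted((c for c in design.channel_map.values() if c > 0),
                   reverse=True)
    rows = []
    for r in records:
        p = r.peptide
        row = {
            "sequence": format_peptide(p) if p else "",
            "type": r.classification,
            "cleaved_aa": events.get(p.sequence if p else "", "-"),
            "Z": predict_charge(p) if p else None,
            "T": count_tags(p) if p else None,
            "theor_m": round(monoisotopic_mass(p), 4) if p else None,
            "flags": ";".join(r.flags),
        }
        for c in concs:
            row[f"ratio_{c:g}nM"] = r.ratios.get(c)
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    data: Iterable[Feature] | Iterable[RatioRecord],
    config: PipelineConfig | None = None,
    library: Sequence[Peptide] | None = None,
) -> PipelineResult:
    """Run the full analysis on LC-MS features or pre-computed ratio records.

    Feature input is grouped into label multiplets, identified against
    ``library`` (when given), quantified and classified; ratio-record
    input skips straight to classification.  Product peptides are linked
    back to library precursors where possible.  Empty input yields an
    empty result with a warning, not an error.
    """
    config = config or PipelineConfig()
    design = config.design
    log: list[dict] = []

    def stage(name: str, **kv) -> None:
        log.append({"stage": name, **{k: str(v) for k, v in kv.items()}})
        logger.info("%s: %s", name, kv)

    data = list(data)
    stage("input", n=len(data), design=dict(design.channel_map),
          seed=config.seed)
    if not data:
        logger.warning("empty input; producing empty report")
        empty = pd.DataFrame()
        return PipelineResult(empty, empty, empty, empty, [], log)

    if isinstance(data[0], Feature):
        sets, singletons = group_peaksets(
            data, design, t_range=config.t_range,
            mz_tol=config.mz_tol_ppm, rt_window=config.rt_window_min)
        stage("group_peaksets", n_sets=len(sets), n_singletons=len(singletons),
              mz_tol_ppm=config.mz_tol_ppm, rt_window_min=config.rt_window_min)
        records = []
        n_unquantified = 0
        for ps in sets:
            if library is not None and ps.peptide is None:
                ps.peptide = identify_peakset(
                    ps, library, tol_ppm=config.parent_tol_ppm)
            if design.control_label not in ps.channel_intensity:
                n_unquantified += 1
                continue
            records.append(compute_ratios(ps, design))
        stage("compute_ratios", n_records=len(records),
              n_without_control=n_unquantified)
    else:
        records = list(data)
        stage("compute_ratios", n_records=len(records), source="precomputed")

    for r in records:
        classify_record(r, design, config.good_cut, config.weak_cut,
                        config.product_cut)
    stage("classify", good_cut=config.good_cut, weak_cut=config.weak_cut,
          product_cut=config.product_cut,
          counts={c: sum(r.classification == c for r in records)
                  for c in set(r.classification for r in records)})

    events: dict[str, str] = {}
    if library is not None:
        for r in records:
            if r.classification == "product" and r.peptide is not None:
                try:
                    ev = link_product(r.peptide, library)
                except AmbiguousPrecursorError as e:
                    stage("link_product_ambiguous", product=str(e))
                    continue
                if ev is not None:
                    events[r.peptide.sequence] = ev.cleaved_aa
        stage("link_products", n_linked=len(events))

    quantified = [r for r in records if r.peptide is not None]
    p1p = build_profile(quantified, position="p1_prime")
    p1 = build_profile(quantified, position="p1",
                       restrict_p1prime=config.permissive_p1prime)
    prefs = preference_summary(p1p)
    stage("profiles", permissive_p1prime=sorted(config.permissive_p1prime),
          n_profiled=len(quantified))

    return PipelineResult(
        report=_report_frame(records, design, events),
        p1_prime_profile=p1p.to_frame(),
        p1_profile=p1.to_frame(),
        preferences=prefs,
        records=records,
        log=log,
    )
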