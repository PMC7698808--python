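"""Grouping of LC-MS features into TMAB label-channel multiplets.

A peptide carrying T tags at charge Z produces one feature per label
channel; consecutive channels are offset in m/z by ``T * delta_label / Z``
where ``delta_label`` is the tag-mass step between the two channels
(3 x (2H-1H) for D0..D9 steps, 3 x (13C-12C) for D9->D12).  Grouping scans
co-eluting features of equal charge for chains with exactly those spacings,
then per-channel intensities are reduced to ratios against the no-enzyme
control channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyteomics import mgf as _mgf

from .masscalc import (
    DEFAULT_CONSTANTS,
    LABELS,
    MassConstants,
    Peptide,
)

__all__ = [
    "Feature",
    "ExperimentDesign",
    "PeakSet",
    "RatioRecord",
    "group_peaksets",
    "compute_ratios",
    "read_features_tsv",
    "write_features_tsv",
    "read_features_mgf",
    "write_features_mgf",
]


@dataclass(frozen=True)
class Feature:
    """A single LC-MS feature (one isotopic-label channel of one peptide)."""

    mz: float
    intensity: float
    retention_time: float
    charge: int | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("mz must be positive")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


@dataclass(frozen=True)
class ExperimentDesign:
    """Maps isotopic labels to enzyme concentrations (nM).

    Exactly one label must map to 0 nM — the no-enzyme control.  The
    5-plex HEK-library screen used D0=100, D3=10, D6=1, D9=0.1, D12=0;
    the 4-plex tryptic screen used D0=0, D3=1, D6=10, D9=100.
    """

    channel_map: Mapping[str, float]
    name: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.channel_map) - set(LABELS)
        if unknown:
            raise ValueError(f"unknown labels: {sorted(unknown)}")
        concs = list(self.channel_map.values())
        if any(c < 0 for c in concs):
            raise ValueError("enzyme concentrations must be >= 0")
        if len(set(concs)) != len(concs):
            raise ValueError("enzyme concentrations must be distinct")
        if sum(1 for c in concs if c == 0) != 1:
            raise ValueError("exactly one label must be the no-enzyme control")

    @property
    def control_label(self) -> str:
        return next(l for l, c in self.channel_map.items() if c == 0)

    @property
    def labels(self) -> tuple[str, ...]:
        """Design labels in canonical (increasing tag mass) order."""
        return tuple(l for l in LABELS if l in self.channel_map)

    @property
    def max_concentration(self) -> float:
        return max(self.channel_map.values())

    @classmethod
    def hek_screen(cls) -> "ExperimentDesign":
        return cls({"D0": 100.0, "D3": 10.0, "D6": 1.0, "D9": 0.1, "D12": 0.0},
                   name="hek_5plex")

    @classmethod
    def tryptic_screen(cls) -> "ExperimentDesign":
        return cls({"D0": 0.0, "D3": 1.0, "D6": 10.0, "D9": 100.0},
                   name="tryptic_4plex")


@dataclass
class PeakSet:
    """One peptide's co-eluting multiplet across label channels."""

    charge: int
    n_tags: int
    channel_intensity: dict[str, float]
    base_mz: float
    retention_time: float = 0.0
    peptide: Peptide | None = None

    def __post_init__(self) -> None:
        if len(self.channel_intensity) < 2:
            raise ValueError("a peak set needs at least 2 channels")


@dataclass
class RatioRecord:
    """Per-concentration intensity ratios vs the no-enzyme control."""

    peptide: Peptide | None
    ratios: dict[float, float]  # enzyme conc (nM) -> intensity ratio
    classification: str = "unclassified"
    flags: tuple[str, ...] = ()

    def ratio_at_max(self) -> float | None:
        if not self.ratios:
            return None
        return self.ratios[max(self.ratios)]


def _tag_steps(constants: MassConstants, labels: Sequence[str]) -> list[float]:
    """Tag-mass difference between consecutive design labels."""
    t = constants.tag_mass
    return [t[b] - t[a] for a, b in zip(labels, labels[1:])]


def group_peaksets(
    features: Iterable[Feature],
    design: ExperimentDesign,
    t_range: Sequence[int] = range(1, 7),
    mz_tol: float = 10.0,
    rt_window: float = 0.5,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> tuple[list[PeakSet], list[Feature]]:
    """Group features into label multiplets.

    For each unassigned feature (in deterministic (rt, mz) order) and each
    tag-count hypothesis ``T`` in ``t_range``, look for co-eluting features
    of the same charge at the expected channel spacings ``T * step / Z``
    within ``mz_tol`` ppm.  A chain covering >= 2 channels becomes a
    :class:`PeakSet`; among competing (T, alignment) hypotheses the one
    with most channels, then smallest summed spacing residual, wins.
    Features enter at most one set; leftovers are returned as singletons.
    """
    feats = sorted(features, key=lambda f: (f.retention_time, f.mz))
    labels = design.labels
    steps = _tag_steps(constants, labels)
    used = [False] * len(feats)
    sets: list[PeakSet] = []

    for i, seed in enumerate(feats):
        if used[i]:
            continue
        z = seed.charge or 1
        best = None  # (n_channels, -residual, T, members)
        for t in t_range:
            if t > z:
                continue
            # hypothesize the seed sits in each possible channel slot
            for seed_slot in range(len(labels)):
                members: dict[int, int] = {seed_slot: i}
                residual = 0.0
                # expected m/z offsets of every slot relative to the seed slot
                for slot in range(len(labels)):
                    if slot == seed_slot:
                        continue
                    lo, hi = sorted((slot, seed_slot))
                    offset = sum(steps[lo:hi]) * t / z
                    target = seed.mz + (offset if slot > seed_slot else -offset)
                    tol = target * mz_tol * 1e-6
                    cand = None
                    for j, f in enumerate(feats):
                        if used[j] or j == i or j in members.values():
                            continue
                        if (f.charge or 1) != z:
                            continue
                        if abs(f.retention_time - seed.retention_time) > rt_window:
                            continue
                        d = abs(f.mz - target)
                        if d <= tol and (cand is None or d < cand[1]):
                            cand = (j, d)
                    if cand is not None:
                        members[slot] = cand[0]
                        residual += cand[1]
                if len(members) >= 2:
                    key = (len(members), -residual)
                    if best is None or key > best[0]:
                        best = (key, t, dict(members))
        if best is None:
            continue
        _, t, members = best
        for j in members.values():
            used[j] = True
        intensities = {labels[slot]: feats[j].intensity for slot, j in members.items()}
        base_slot = min(members)
        base = feats[members[base_slot]]
        sets.append(
            PeakSet(
                charge=z,
                n_tags=t,
                channel_intensity=intensities,
                base_mz=base.mz,
                retention_time=seed.retention_time,
            )
        )
    singletons = [f for j, f in enumerate(feats) if not used[j]]
    return sets, singletons


def compute_ratios(ps: PeakSet, design: ExperimentDesign) -> RatioRecord:
    """Reduce channel intensities to enzyme/no-enzyme ratios.

    Missing channels propagate as missing ratios (rendered "n.d." in
    reports); a missing or zero control channel is an error since nothing
    can be normalized.
    """
    control = design.control_label
    c = ps.channel_intensity.get(control)
    if c is None or c <= 0:
        raise ValueError(
            f"peak set at m/z {ps.base_mz:.4f}: control channel {control} "
            "missing or non-positive"
        )
    ratios = {
        design.channel_map[label]: ps.channel_intensity[label] / c
        for label in design.labels
        if label != control and label in ps.channel_intensity
    }
    return RatioRecord(peptide=ps.peptide, ratios=ratios)


# ---------------------------------------------------------------------------
# Feature I/O — TSV and MGF-style peak lists

_FEATURE_COLS = ["mz", "intensity", "rt", "charge"]


def write_features_tsv(features: Iterable[Feature], path: str | Path) -> None:
    df = pd.DataFrame(
        [(f.mz, f.intensity, f.retention_time, f.charge) for f in features],
        columns=_FEATURE_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_features_tsv(path: str | Path) -> list[Feature]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_FEATURE_COLS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for idx, row in df.iterrows():
        try:
            charge = None if "charge" not in df.columns or pd.isna(row.get("charge")) else int(row["charge"])
            out.append(Feature(float(row["mz"]), float(row["intensity"]),
                               float(row["rt"]), charge))
        except (ValueError, TypeError) as e:
            raise ValueError(f"{path}: line {idx + 2}: {e}") from None
    return out


def write_features_mgf(features: Iterable[Feature], path: str | Path) -> None:
    """Write features as one-peak MGF spectra (PEPMASS carries m/z+intensity)."""
    spectra = []
    for k, f in enumerate(features):
        params = {
            "title": f"feature_{k}",
            "pepmass": (f.mz, f.intensity),
            "rtinseconds": f.retention_time * 60.0,
        }
        if f.charge:
            params["charge"] = f.charge
        spectra.append({"params": params, "m/z array": [], "intensity array": []})
    _mgf.write(spectra, str(path), file_mode="w")


def read_features_mgf(path: str | Path) -> list[Feature]:
    out = []
    with _mgf.MGF(str(path)) as reader:
        for spec in reader:
            p = spec["params"]
            mz, intensity = p["pepmass"][0], p["pepmass"][1] or 0.0
            rt = float(p.get("rtinseconds", 0.0)) / 60.0
            charge = int(p["charge"][0]) if "charge" in p else None
            out.append(Feature(mz, intensity, rt, charge))
    return out
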