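"""Quantitative pollen-load coding of floral-host characters.

Raw per-sample scopal pollen compositions are turned into per-species
profiles and then into binary characters for downstream ancestral-state and
diversification analyses.  Two character systems are supported:

* pollen *accessibility* — whether a species collects pollen presented
  openly on visible anthers (accessible, ``A``) or concealed inside
  structurally complex bee-flowers (restricted, ``R``), with mixed carriage
  scored polymorphic (``AR``);
* pollen *specificity* — oligolectic specialists (>= 95% of carried grains
  from one plant family, optionally genus) versus polylectic generalists.

Minor pollen types below 5% of each individual sample are treated as
contamination and excluded *before* samples are combined, so that pooling
many samples cannot dilute a contaminant below detection.  Samples are
combined weighting each by the original pollen-load size.

The accessibility states resolve to tip states under four named partitions:

========= ==============================================================
partition  coding
========= ==============================================================
``PA1``    A -> 0, R -> 1, AR -> 1 (polymorphics scored restricted)
``PA2``    A -> 0, R -> 1, AR -> ambiguous
``PA3``    A -> 0, R -> 1, AR -> 0 (polymorphics scored accessible)
``PS``     specialist -> 0, generalist -> 1
========= ==============================================================

Data-deficient species are coded missing in every partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import EmptyProfileError, InputError

__all__ = [
    "ACCESSIBLE",
    "RESTRICTED",
    "PollenSample",
    "CatalogEntry",
    "PollenCatalog",
    "SpeciesProfile",
    "CharacterMatrix",
    "aggregate_species_profile",
    "classify_accessibility",
    "classify_specificity",
    "build_character_matrix",
    "code_species_states",
    "read_pollen_samples_csv",
    "read_catalog_csv",
]

MINOR_TYPE_THRESHOLD = 0.05  # contamination cutoff, per individual sample
SPECIALIST_THRESHOLD = 0.95  # inclusive: ">= 95% from one family"

ACCESSIBLE = "accessible"
RESTRICTED = "restricted"
UNKNOWN = "unknown"

PARTITIONS = ("PA1", "PA2", "PA3", "PS")

#: Legal per-tip states in a character matrix.
STATE_0 = "0"
STATE_1 = "1"
AMBIGUOUS = "ambiguous"
MISSING = "missing"


@dataclass(frozen=True)
class PollenSample:
    """One scopal pollen load: percentage composition over pollen types.

    ``load_weight`` is the original pollen-load size class assigned before
    grain removal; it weights this sample when samples are pooled.  Records
    compiled from literature carry no load size and default to weight 1.
    """

    species: str
    sample_id: str
    composition: Mapping[str, float]
    load_weight: float = 1.0

    def __post_init__(self):
        if self.load_weight <= 0:
            raise InputError(f"load_weight must be positive, got {self.load_weight}")
        if not self.composition:
            raise InputError(f"sample {self.sample_id}: empty composition")
        total = 0.0
        for ptype, pct in self.composition.items():
            if pct < 0:
                raise InputError(
                    f"sample {self.sample_id}: negative percentage for {ptype}"
                )
            total += pct
        if not 99.0 <= total <= 101.0:
            raise InputError(
                f"sample {self.sample_id}: percentages sum to {total:.3f}, "
                "expected ~100"
            )


@dataclass(frozen=True)
class CatalogEntry:
    plant_family: str
    accessibility: str  # accessible | restricted | unknown
    plant_genus: str | None = None

    def __post_init__(self):
        if self.accessibility not in (ACCESSIBLE, RESTRICTED, UNKNOWN):
            raise InputError(f"bad accessibility {self.accessibility!r}")


class PollenCatalog:
    """Maps pollen types to plant family/genus and reward accessibility."""

    def __init__(self, entries: Mapping[str, CatalogEntry]):
        self._entries = dict(entries)

    def __contains__(self, pollen_type: str) -> bool:
        return pollen_type in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def accessibility(self, pollen_type: str) -> str:
        entry = self._entries.get(pollen_type)
        return entry.accessibility if entry is not None else UNKNOWN

    def family(self, pollen_type: str) -> str | None:
        entry = self._entries.get(pollen_type)
        return entry.plant_family if entry is not None else None

    def genus(self, pollen_type: str) -> str | None:
        entry = self._entries.get(pollen_type)
        return entry.plant_genus if entry is not None else None

    def items(self):
        return self._entries.items()


@dataclass(frozen=True)
class SpeciesProfile:
    """Load-weighted pollen-type proportions for one bee species."""

    species: str
    proportions: Mapping[str, float]
    n_samples: int

    def __post_init__(self):
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise InputError(
                f"profile {self.species}: proportions sum to {total}, expected 1"
            )


def _filter_minor_types(shares: dict[str, float], threshold: float) -> dict[str, float]:
    kept = {t: s for t, s in shares.items() if s >= threshold}
    if not kept:
        raise EmptyProfileError("all pollen types fell below the minor-type threshold")
    total = sum(kept.values())
    return {t: s / total for t, s in kept.items()}


def aggregate_species_profile(
    samples: Iterable[PollenSample],
    minor_threshold: float = MINOR_TYPE_THRESHOLD,
) -> SpeciesProfile:
    """Pool samples of one species into a load-weighted profile.

    Each sample is first cleaned of minor types (< ``minor_threshold`` of that
    sample, i.e. the "< 5% of each pollen sample" contamination rule) and
    renormalised, then samples are averaged with weights proportional to
    ``load_weight``.
    """
    samples = list(samples)
    if not samples:
        raise InputError("no samples given")
    species = {s.species for s in samples}
    if len(species) != 1:
        raise InputError(f"samples mix species: {sorted(species)}")
    total_weight = sum(s.load_weight for s in samples)
    pooled: dict[str, float] = {}
    for s in samples:
        shares = {t: p / 100.0 for t, p in s.composition.items()}
        shares = {t: v / sum(shares.values()) for t, v in shares.items()}
        clean = _filter_minor_types(shares, minor_threshold)
        w = s.load_weight / total_weight
        for t, v in clean.items():
            pooled[t] = pooled.get(t, 0.0) + w * v
    total = sum(pooled.values())
    pooled = {t: v / total for t, v in pooled.items()}
    return SpeciesProfile(
        species=samples[0].species, proportions=pooled, n_samples=len(samples)
    )


def classify_accessibility(
    profile: SpeciesProfile,
    catalog: PollenCatalog,
    minor_threshold: float = MINOR_TYPE_THRESHOLD,
) -> str:
    """Code a species profile as ``A``, ``R``, ``AR`` or ``data_deficient``.

    A species is polymorphic (``AR``) when both reward categories each exceed
    the minor-type threshold of the pooled profile; types of unknown
    accessibility exceeding that threshold make the species data deficient.
    """
    if not profile.proportions:
        raise InputError("empty profile")
    share = {ACCESSIBLE: 0.0, RESTRICTED: 0.0, UNKNOWN: 0.0}
    for ptype, p in profile.proportions.items():
        share[catalog.accessibility(ptype)] += p
    if share[UNKNOWN] > minor_threshold:
        return "data_deficient"
    both = share[ACCESSIBLE] > minor_threshold and share[RESTRICTED] > minor_threshold
    if both:
        return "AR"
    return "A" if share[ACCESSIBLE] >= share[RESTRICTED] else "R"


def classify_specificity(
    profile: SpeciesProfile,
    catalog: PollenCatalog,
    threshold: float = SPECIALIST_THRESHOLD,
    level: str = "family",
) -> str:
    """Code as ``specialist`` (oligolectic) or ``generalist`` (polylectic).

    A species is a specialist when the largest single plant family (or genus,
    with ``level='genus'``) holds at least ``threshold`` of the carried
    pollen; the boundary is inclusive.  Returns ``'data_deficient'`` when the
    catalog cannot resolve the grouping level for the carried types.
    """
    if level not in ("family", "genus"):
        raise InputError(f"level must be 'family' or 'genus', got {level!r}")
    groups: dict[str, float] = {}
    for ptype, p in profile.proportions.items():
        key = catalog.family(ptype) if level == "family" else catalog.genus(ptype)
        if key is None:
            return "data_deficient"
        groups[key] = groups.get(key, 0.0) + p
    return "specialist" if max(groups.values()) >= threshold else "generalist"


_PA_CODING = {
    "PA1": {"A": STATE_0, "R": STATE_1, "AR": STATE_1},
    "PA2": {"A": STATE_0, "R": STATE_1, "AR": AMBIGUOUS},
    "PA3": {"A": STATE_0, "R": STATE_1, "AR": STATE_0},
}
_PS_CODING = {"specialist": STATE_0, "generalist": STATE_1}


@dataclass(frozen=True)
class CharacterMatrix:
    """Binary tip states under one named partition.

    ``states`` maps tip label to one of ``'0'``, ``'1'``, ``'ambiguous'``,
    ``'missing'``.  Ambiguous and missing tips both contribute flat partial
    likelihoods; the distinction is kept for reporting.
    """

    partition: str
    states: Mapping[str, str]

    def __post_init__(self):
        if self.partition not in PARTITIONS:
            raise InputError(
                f"unknown partition {self.partition!r}; expected one of {PARTITIONS}"
            )
        legal = {STATE_0, STATE_1, AMBIGUOUS, MISSING}
        for tip, st in self.states.items():
            if st not in legal:
                raise InputError(f"illegal state {st!r} for tip {tip!r}")

    def state_codes(self, tip_labels: Iterable[str]) -> "np.ndarray":
        """Integer codes per tip: 0, 1, or 2 for ambiguous/missing.

        Tips absent from the matrix are coded 2 (missing).
        """
        import numpy as np

        codes = []
        for tip in tip_labels:
            st = self.states.get(tip, MISSING)
            codes.append({STATE_0: 0, STATE_1: 1}.get(st, 2))
        return np.asarray(codes, dtype=np.int64)

    def counts(self) -> dict[str, int]:
        out = {STATE_0: 0, STATE_1: 0, AMBIGUOUS: 0, MISSING: 0}
        for st in self.states.values():
            out[st] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tip": list(self.states), "state": list(self.states.values())}
        )

    def to_nexus(self) -> str:
        """NEXUS CHARACTERS block; ambiguous as {01}, missing as ?."""
        sym = {STATE_0: "0", STATE_1: "1", AMBIGUOUS: "{01}", MISSING: "?"}
        rows = "\n".join(
            f"    {_nexus_label(t)} {sym[s]}" for t, s in self.states.items()
        )
        return (
            "#NEXUS\nBEGIN CHARACTERS;\n"
            f"  DIMENSIONS NTAX={len(self.states)} NCHAR=1;\n"
            '  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n'
            f"  MATRIX\n{rows}\n  ;\nEND;\n"
        )


def _nexus_label(label: str) -> str:
    if any(c in label for c in " ()[]{}:;,'\""):
        return "'" + label.replace("'", "''") + "'"
    return label


def build_character_matrix(
    species_states: Mapping[str, str], partition: str
) -> CharacterMatrix:
    """Resolve per-species trait codes to binary tip states for a partition.

    Accessibility partitions (PA1-3) expect states in
    ``{A, R, AR, data_deficient}``; the specificity partition (PS) expects
    ``{specialist, generalist, data_deficient}``.
    """
    if partition in _PA_CODING:
        coding = _PA_CODING[partition]
    elif partition == "PS":
        coding = _PS_CODING
    else:
        raise InputError(f"unknown partition {partition!r}")
    states: dict[str, str] = {}
    for species, st in species_states.items():
        if st == "data_deficient":
            states[species] = MISSING
        elif st in coding:
            states[species] = coding[st]
        else:
            raise InputError(
                f"state {st!r} for {species!r} is not legal under {partition}"
            )
    return CharacterMatrix(partition=partition, states=states)


def code_species_states(
    samples: Iterable[PollenSample],
    catalog: PollenCatalog,
    character: str = "accessibility",
    minor_threshold: float = MINOR_TYPE_THRESHOLD,
    specialist_threshold: float = SPECIALIST_THRESHOLD,
    level: str = "family",
) -> dict[str, str]:
    """Full coding pipeline: samples -> profiles -> per-species trait states."""
    if character not in ("accessibility", "specificity"):
        raise InputError(f"unknown character {character!r}")
    by_species: dict[str, list[PollenSample]] = {}
    for s in samples:
        by_species.setdefault(s.species, []).append(s)
    out: dict[str, str] = {}
    for species, group in by_species.items():
        profile = aggregate_species_profile(group, minor_threshold)
        if character == "accessibility":
            out[species] = classify_accessibility(profile, catalog, minor_threshold)
        else:
            out[species] = classify_specificity(
                profile, catalog, specialist_threshold, level
            )
    return out


# ----------------------------------------------------------------------
# file I/O
# ----------------------------------------------------------------------
def read_pollen_samples_csv(path) -> list[PollenSample]:
    """Long-format table: species, sample_id, [load_weight], pollen_type, percent."""
    df = pd.read_csv(path)
    required = {"species", "sample_id", "pollen_type", "percent"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"pollen table missing columns: {sorted(missing)}")
    if "load_weight" not in df.columns:
        df = df.assign(load_weight=1.0)
    df["load_weight"] = df["load_weight"].fillna(1.0)
    samples = []
    for (species, sample_id), grp in df.groupby(["species", "sample_id"], sort=False):
        weights = grp["load_weight"].unique()
        if len(weights) != 1:
            raise InputError(
                f"sample {sample_id!r}: inconsistent load_weight values"
            )
        samples.append(
            PollenSample(
                species=str(species),
                sample_id=str(sample_id),
                load_weight=float(weights[0]),
                composition=dict(zip(grp["pollen_type"], grp["percent"].astype(float))),
            )
        )
    return samples


def read_catalog_csv(path) -> PollenCatalog:
    """Catalog table: pollen_type, plant_family, accessibility, [plant_genus]."""
    df = pd.read_csv(path)
    required = {"pollen_type", "plant_family", "accessibility"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"catalog missing columns: {sorted(missing)}")
    entries = {}
    for _, row in df.iterrows():
        genus = row.get("plant_genus")
        entries[str(row["pollen_type"])] = CatalogEntry(
            plant_family=str(row["plant_family"]),
            accessibility=str(row["accessibility"]),
            plant_genus=None if pd.isna(genus) else str(genus),
        )
    return PollenCatalog(entries)
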