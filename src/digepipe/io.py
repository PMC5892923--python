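"""Data model, validation and file I/O for 2D-DIGE experiments.

A difference-gel-electrophoresis (DIGE) experiment co-resolves three
fluorescently labelled protein mixtures on each gel: a pooled internal
standard (an equal mix of every sample in the study, conventionally the Cy2
channel) plus two biological samples (Cy3/Cy5).  Here the two samples on a
gel are always the high- and low-spiking cortical tissue of one patient, and
each patient contributes two gels per subcellular fraction with the dye
assignment swapped between them (dye-swap technical replicates).

This module defines the validated containers the rest of the pipeline works
on -- study designs, spot-volume tables, patient metadata, spot annotations
and gene-set collections -- together with plain-text readers/writers
(CSV/TSV for tables, YAML/JSON for designs, GMT for gene sets).  Spot ids
and gel ids are opaque strings; gene symbols are upper-cased on ingest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

STANDARD_DYE = "std"
SAMPLE_DYES = ("A", "B")
DYES = (STANDARD_DYE,) + SAMPLE_DYES
CONDITIONS = ("high", "low")
FRACTIONS = ("P1_nuclear", "P2_membrane", "cytosol")
STANDARD_LABEL = "standard"
CONFIDENCE_LEVELS = (
    "identified_ms",       # '$' : MS identification, single protein, multiple peptides
    "inferred_single",     # '*' : inferred, one candidate protein
    "inferred_multiple",   # '/' : inferred, several candidate proteins
    "unidentified",
)
HISTOPATHOLOGY_GRADES = ("normal", "diffuse", "mild", "subcortical")

#: separator used to flatten (gel_id, dye) column pairs in delimited files
COLUMN_SEP = ":"


class DigeError(Exception):
    """Base class for all errors raised by digepipe."""


class DesignError(DigeError):
    """A study design violates its invariants."""


class FormatError(DigeError):
    """A file or table cannot be parsed or fails validation."""


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


# ---------------------------------------------------------------------------
# Study design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GelRecord:
    """One analytical gel: three dye channels imaged from the same slab.

    ``channels`` maps each dye in :data:`DYES` to the label of what it
    carries: the pooled internal standard (``"standard"``) or one of the
    patient's two conditions (``"high"``/``"low"``).
    """

    gel_id: str
    fraction: str
    patient_id: str
    channels: Mapping[str, str]

    def __post_init__(self) -> None:
        dyes = tuple(sorted(self.channels))
        if dyes != tuple(sorted(DYES)):
            raise DesignError(
                f"gel {self.gel_id!r}: channels must cover dyes {DYES}, got {dyes}"
            )
        if self.channels[STANDARD_DYE] != STANDARD_LABEL:
            raise DesignError(
                f"gel {self.gel_id!r}: dye {STANDARD_DYE!r} must carry the "
                f"pooled standard, got {self.channels[STANDARD_DYE]!r}"
            )
        conds = {self.channels[d] for d in SAMPLE_DYES}
        if conds != set(CONDITIONS):
            raise DesignError(
                f"gel {self.gel_id!r}: sample dyes must carry one 'high' and "
                f"one 'low' sample, got {sorted(conds)}"
            )

    @property
    def orientation(self) -> str:
        """Condition carried by dye A ('high' or 'low'); flips across a dye swap."""
        return self.channels["A"]


@dataclass
class StudyDesign:
    """Maps every (gel, dye channel) to its patient/condition/fraction."""

    gels: list[GelRecord]

    def __post_init__(self) -> None:
        ids = [g.gel_id for g in self.gels]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise DesignError(f"duplicate gel ids: {sorted(dup)}")
        self._by_id = {g.gel_id: g for g in self.gels}

    def fractions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for g in self.gels:
            seen.setdefault(g.fraction, None)
        return tuple(seen)

    def patients(self, fraction: str | None = None) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for g in self.gels:
            if fraction is None or g.fraction == fraction:
                seen.setdefault(g.patient_id, None)
        return tuple(seen)

    def gels_for(self, fraction: str) -> list[GelRecord]:
        return [g for g in self.gels if g.fraction == fraction]

    def gel(self, gel_id: str) -> GelRecord:
        try:
            return self._by_id[gel_id]
        except KeyError:
            raise DesignError(f"unknown gel id {gel_id!r}") from None

    def columns(self, fraction: str) -> list[tuple[str, str]]:
        """(gel_id, dye) pairs for every analytical image of a fraction."""
        return [(g.gel_id, dye) for g in self.gels_for(fraction) for dye in DYES]

    def sample_of(self, gel_id: str, dye: str) -> tuple[str, str] | None:
        """(patient, condition) carried by a channel; None for the standard."""
        g = self.gel(gel_id)
        label = g.channels[dye]
        if label == STANDARD_LABEL:
            return None
        return (g.patient_id, label)

    def replicate_gels(self, fraction: str, patient_id: str) -> list[GelRecord]:
        return [g for g in self.gels_for(fraction) if g.patient_id == patient_id]


def validate_design(design: StudyDesign) -> dict:
    """Check design invariants and return per-fraction counts.

    Returns ``{fraction: {"gels": n, "images": 3n, "patients": k}}`` with an
    additional ``"total"`` entry.  Raises :class:`DesignError` if a patient
    lacks a dye-swap partner in some fraction, if the replicate gels of a
    patient are not reciprocally labelled, or if the patient set differs
    between fractions.
    """
    if not design.gels:
        raise DesignError("design contains no gels")
    report: dict = {}
    patient_sets = {}
    for fraction in design.fractions():
        gels = design.gels_for(fraction)
        patients = design.patients(fraction)
        patient_sets[fraction] = set(patients)
        for p in patients:
            reps = design.replicate_gels(fraction, p)
            if len(reps) < 2:
                raise DesignError(
                    f"patient {p!r}, fraction {fraction!r}: dye-swap pair missing "
                    f"(only {len(reps)} gel)"
                )
            n_high = sum(g.orientation == "high" for g in reps)
            n_low = len(reps) - n_high
            if n_high != n_low:
                raise DesignError(
                    f"patient {p!r}, fraction {fraction!r}: replicate gels are "
                    f"not reciprocal ({n_high} with A=high vs {n_low} with A=low)"
                )
        report[fraction] = {
            "gels": len(gels),
            "images": 3 * len(gels),
            "patients": len(patients),
        }
    if len(set(map(frozenset, patient_sets.values()))) > 1:
        raise DesignError(f"patient sets differ between fractions: {patient_sets}")
    report["total"] = {
        "gels": len(design.gels),
        "images": 3 * len(design.gels),
        "patients": len(design.patients()),
    }
    return report


def design_to_dict(design: StudyDesign) -> dict:
    return {
        "gels": [
            {
                "gel_id": g.gel_id,
                "fraction": g.fraction,
                "patient_id": g.patient_id,
                "channels": dict(g.channels),
            }
            for g in design.gels
        ]
    }


def design_from_dict(payload: Mapping) -> StudyDesign:
    try:
        gels = [
            GelRecord(
                gel_id=str(rec["gel_id"]),
                fraction=str(rec["fraction"]),
                patient_id=str(rec["patient_id"]),
                channels={str(k): str(v) for k, v in rec["channels"].items()},
            )
            for rec in payload["gels"]
        ]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed design record: {exc}") from exc
    return StudyDesign(gels=gels)


def read_design(path: str | Path) -> StudyDesign:
    """Read a study design from YAML (.yaml/.yml) or JSON (.json)."""
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return design_from_dict(payload)


def write_design(design: StudyDesign, path: str | Path) -> None:
    path = Path(path)
    payload = design_to_dict(design)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


# ---------------------------------------------------------------------------
# Spot-volume tables
# ---------------------------------------------------------------------------

@dataclass
class SpotVolumeTable:
    """Raw fluorescence spot volumes for one subcellular fraction.

    ``volumes`` is indexed by spot id with a ``(gel_id, dye)`` MultiIndex on
    the columns; every value is a strictly positive fluorescence volume.
    """

    fraction: str
    volumes: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, design: StudyDesign | None = None) -> None:
        vol = self.volumes
        if vol.index.has_duplicates:
            dups = vol.index[vol.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate spot ids: {dups}")
        if vol.isna().any().any():
            bad = vol.columns[vol.isna().any()][0]
            raise FormatError(f"missing volume in column {bad}")
        arr = vol.to_numpy()
        if (arr <= 0).any():
            i, j = np.argwhere(arr <= 0)[0]
            raise FormatError(
                f"non-positive volume for spot {vol.index[i]!r} in column "
                f"{vol.columns[j]} ({arr[i, j]!r})"
            )
        if design is not None:
            expected = set(design.columns(self.fraction))
            got = set(map(tuple, vol.columns))
            if expected != got:
                missing = sorted(expected - got)
                extra = sorted(got - expected)
                raise FormatError(
                    f"fraction {self.fraction!r}: columns do not match design "
                    f"(missing {missing}, unexpected {extra})"
                )

    @property
    def spot_ids(self) -> list[str]:
        return list(self.volumes.index)


def _flatten_columns(columns: Iterable[tuple[str, str]]) -> list[str]:
    return [f"{gel}{COLUMN_SEP}{dye}" for gel, dye in columns]


def _split_column(name: str) -> tuple[str, str]:
    if COLUMN_SEP not in name:
        raise FormatError(
            f"column {name!r} is not of the form 'gel{COLUMN_SEP}dye'"
        )
    gel, dye = name.rsplit(COLUMN_SEP, 1)
    if dye not in DYES:
        raise FormatError(f"column {name!r}: unknown dye {dye!r}")
    return gel, dye


def read_spot_table(
    path: str | Path,
    design: StudyDesign | None = None,
    fraction: str | None = None,
) -> SpotVolumeTable:
    """Read a delimited spot-volume table.

    The file must have a ``spot_id`` column and one column per analytical
    image named ``<gel_id>:<dye>``.  When ``design`` is given, the fraction
    is inferred by matching the column set against the design (and the table
    is reconciled against it); otherwise ``fraction`` must be supplied.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if "spot_id" not in df.columns:
        raise FormatError(f"{path}: missing required 'spot_id' column")
    df["spot_id"] = df["spot_id"].astype(str)
    df = df.set_index("spot_id")
    pairs = [_split_column(c) for c in df.columns]
    df.columns = pd.MultiIndex.from_tuples(pairs, names=["gel_id", "dye"])
    df = df.astype(float)
    if design is not None:
        got = set(map(tuple, df.columns))
        matches = [f for f in design.fractions() if set(design.columns(f)) == got]
        if fraction is not None:
            if fraction not in design.fractions():
                raise FormatError(f"fraction {fraction!r} not present in design")
            matches = [fraction] if fraction in matches else []
        if not matches:
            raise FormatError(
                f"{path}: columns do not match any fraction of the design"
            )
        fraction = matches[0]
    elif fraction is None:
        raise FormatError("either a design or an explicit fraction is required")
    table = SpotVolumeTable(fraction=fraction, volumes=df)
    table.validate(design)
    return table


def write_spot_table(table: SpotVolumeTable, path: str | Path) -> None:
    path = Path(path)
    out = table.volumes.copy()
    out.columns = _flatten_columns(out.columns)
    out.index.name = "spot_id"
    out.to_csv(path, sep=_sep_for(path))


# ---------------------------------------------------------------------------
# Patient metadata
# ---------------------------------------------------------------------------

@dataclass
class PatientMetadata:
    """Per-patient clinical covariates.

    ``table`` is indexed by patient id with columns ``gender``, ``age``,
    ``spike_high``, ``spike_low`` (interictal spike frequencies of the two
    tissue blocks, carried in whatever unit they were recorded in) and
    ``histopathology`` (one of :data:`HISTOPATHOLOGY_GRADES`).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gender", "age", "spike_high", "spike_low", "histopathology"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"patient metadata missing columns: {sorted(missing)}")
        t = self.table
        bad = t.index[(t["spike_high"] < t["spike_low"]) | (t["spike_low"] < 0)]
        if len(bad):
            raise FormatError(
                f"patients {list(bad)}: require spike_high >= spike_low >= 0"
            )
        unknown = set(t["histopathology"]) - set(HISTOPATHOLOGY_GRADES)
        if unknown:
            raise FormatError(f"unknown histopathology grades: {sorted(unknown)}")

    @property
    def delta_spike(self) -> pd.Series:
        """High-minus-low spike-frequency difference per patient."""
        d = self.table["spike_high"] - self.table["spike_low"]
        d.name = "delta_spike"
        return d

    @property
    def patients(self) -> list[str]:
        return list(self.table.index)


def read_patient_table(path: str | Path) -> PatientMetadata:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col="patient_id")
    df.index = df.index.astype(str)
    return PatientMetadata(table=df)


def write_patient_table(metadata: PatientMetadata, path: str | Path) -> None:
    path = Path(path)
    out = metadata.table.copy()
    out.index.name = "patient_id"
    out.to_csv(path, sep=_sep_for(path))


# ---------------------------------------------------------------------------
# Spot annotation
# ---------------------------------------------------------------------------

@dataclass
class SpotAnnotation:
    """Spot-to-protein assignments with identification-confidence codes.

    One row per (fraction, spot): nullable ``gene_symbol``, a confidence
    level from :data:`CONFIDENCE_LEVELS`, an ``isoform_group`` id shared by
    the spots of one protein's isoform train, and an optional ``mw_class``
    tag (e.g. ``GFAP_50kDa`` vs ``GFAP_LMW``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"fraction", "spot_id", "gene_symbol", "confidence",
                    "isoform_group", "mw_class"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"annotation missing columns: {sorted(missing)}")
        t = self.table
        t["gene_symbol"] = t["gene_symbol"].str.upper()
        unknown = set(t["confidence"]) - set(CONFIDENCE_LEVELS)
        if unknown:
            raise FormatError(f"unknown confidence codes: {sorted(unknown)}")
        unid = t["confidence"] == "unidentified"
        if t.loc[unid, "gene_symbol"].notna().any():
            bad = t.loc[unid & t["gene_symbol"].notna(), "spot_id"].tolist()
            raise FormatError(f"unidentified spots with a gene symbol: {bad}")
        genes_per_group = (
            t.dropna(subset=["gene_symbol"]).groupby("isoform_group")["gene_symbol"].nunique()
        )
        multi = genes_per_group[genes_per_group > 1]
        if len(multi):
            raise FormatError(
                f"isoform groups mapping to several genes: {list(multi.index)}"
            )

    def genes(self) -> set[str]:
        return set(self.table["gene_symbol"].dropna())

    def spots_for_gene(
        self,
        gene_symbol: str,
        fraction: str | None = None,
        mw_class: str | None = None,
    ) -> list[str]:
        t = self.table
        mask = t["gene_symbol"] == gene_symbol.upper()
        if fraction is not None:
            mask &= t["fraction"] == fraction
        if mw_class is not None:
            mask &= t["mw_class"] == mw_class
        return t.loc[mask, "spot_id"].tolist()

    def gene_of(self) -> pd.Series:
        """Series mapping (fraction, spot_id) -> gene symbol (NaN if unknown)."""
        return self.table.set_index(["fraction", "spot_id"])["gene_symbol"]


def read_annotation(path: str | Path) -> SpotAnnotation:
    df = pd.read_csv(Path(path), sep=_sep_for(Path(path)), dtype={"spot_id": str})
    return SpotAnnotation(table=df)


def write_annotation(annotation: SpotAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(Path(path), sep=_sep_for(Path(path)), index=False)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets over a finite background ("universe") of symbols.

    Symbols are upper-cased; members outside the universe are dropped at
    construction so that set membership and the hypergeometric background
    agree.  Descriptions are carried only for GMT round-trips.
    """

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.universe = frozenset(g.upper() for g in self.universe)
        harmonized: dict[str, frozenset[str]] = {}
        for name, members in self.sets.items():
            kept = frozenset(g.upper() for g in members) & self.universe
            if not kept:
                raise FormatError(
                    f"gene set {name!r} is empty after harmonization with the universe"
                )
            harmonized[name] = kept
        self.sets = harmonized

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (tab-separated: name, description, members...).

    Without an explicit ``universe`` the background defaults to the union of
    all set members.  Duplicate members are stored once.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
            )
        name, desc, *members = fields
        sets[name] = frozenset(m.upper() for m in members if m)
        descriptions[name] = desc
    if universe is None:
        universe = frozenset().union(*sets.values()) if sets else frozenset()
    return GeneSetCollection(sets=sets, universe=frozenset(universe),
                             descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name, members in collection.sets.items():
        desc = collection.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *sorted(members)]))
    Path(path).write_text("\n".join(lines) + "\n")
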