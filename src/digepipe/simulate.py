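"""Synthetic DIGE datasets with known ground truth.

The raw gel data this pipeline was designed around are not publicly
deposited, so every downstream stage is exercised on simulated studies that
reproduce the statistical structure the analysis assumes:

* 6 patients x 2 conditions (high/low interictal spiking) x 2 dye-swap gels
  x 3 channels (Cy2 pooled standard + two samples) per subcellular fraction;
* spot abundances log10-normal across spots, with per-sample biological
  variation shared along isoform spot trains;
* a pooled-standard channel that is the arithmetic mean of all samples'
  true abundances for each spot;
* multiplicative log-normal technical noise and a per-image gain;
* planted differential spots with a common signed ln fold change across
  patients;
* marker clusters (erythrocyte, fibrinogen, smooth-muscle, plasma panels)
  driven by independent latent per-sample factors, the erythrocyte factor
  playing the role of tissue vascularity;
* a GFAP-like nuclear protein (six ~50 kDa isoform spots plus five
  low-molecular-weight fragments) whose per-patient fold change (low/high)
  is a strictly increasing linear function of the patient's spike-frequency
  difference, and whose cytosolic pool tracks a per-patient gliosis level.

Everything is deterministic given the seed; each fraction draws from its
own named substream so partial re-runs reproduce exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import DEFAULT_MARKER_PANELS, MarkerPanel
from .io import (
    CONDITIONS,
    FRACTIONS,
    SAMPLE_DYES,
    STANDARD_DYE,
    STANDARD_LABEL,
    DigeError,
    GelRecord,
    GeneSetCollection,
    PatientMetadata,
    SpotAnnotation,
    SpotVolumeTable,
    StudyDesign,
)

#: subcellular fraction each marker panel's spots are placed in
MARKER_FRACTIONS = {
    "erythrocyte": "cytosol",
    "plasma": "cytosol",
    "fibrinogen": "cytosol",
    "smooth_muscle": "P2_membrane",
}

#: cytosol/nuclear GFAP concentration ratio anchors per histopathology grade
GLIOSIS_RATIO_BY_GRADE = {
    "normal": 0.22,
    "mild": 0.5,
    "subcortical": 0.8,
    "diffuse": 1.0,
}

_FR_CODE = {"P1_nuclear": "P1", "P2_membrane": "P2", "cytosol": "CY"}


def default_cohort() -> PatientMetadata:
    """The six-patient refractory-epilepsy cohort the generator emulates.

    Interictal spike frequencies (high/low block) and histopathology grade
    per patient; spike-frequency units are carried opaquely.
    """
    table = pd.DataFrame(
        {
            "gender": ["F", "F", "M", "M", "M", "F"],
            "age": [15, 10, 33, 1, 27, 3],
            "spike_high": [6, 116, 371, 85, 27, 212],
            "spike_low": [0, 1, 115, 0, 2, 56],
            "histopathology": ["normal", "diffuse", "normal", "subcortical",
                               "mild", "mild"],
        },
        index=pd.Index(["ep122", "ep132", "ep150", "ep158", "ep159", "ep165"],
                       name="patient_id"),
    )
    return PatientMetadata(table=table)


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the emulated study's conditions."""

    n_patients: int = 6
    fractions: tuple[str, ...] = FRACTIONS
    n_spots: int = 1500
    baseline_log10_mean: float = 4.0
    baseline_log10_sd: float = 0.5
    #: per-(spot, sample) biological variation, log10 scale
    biological_sd: float = 0.05
    #: multiplicative log-normal technical noise, as a coefficient of variation
    technical_cv: float = 0.10
    gain_range: tuple[float, float] = (0.5, 2.0)
    n_differential: int = 40
    differential_lnfc: float = math.log(1.6)
    #: largest isoform spot train; 1 disables co-varying trains
    isoform_train_max: int = 11
    #: probability an ordinary protein has a multi-spot train
    multi_train_prob: float = 0.3
    #: correlation of biological variation within a train
    isoform_correlation: float = 0.8
    marker_panels: tuple[MarkerPanel, ...] = DEFAULT_MARKER_PANELS
    #: marker loading amplitude in units of biological_sd
    marker_snr: float = 5.0
    include_gfap: bool = True
    #: planted FC(low/high) = gfap_slope * delta_spike + gfap_intercept
    gfap_slope: float = 1.0 / 200.0
    gfap_intercept: float = 251.0 / 200.0
    #: optional log10 jitter on the planted GFAP relation (0 keeps it exact)
    gfap_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_log10_sd <= 0:
            raise DigeError("baseline_log10_sd must be positive")
        if self.biological_sd < 0:
            raise DigeError("biological_sd must be >= 0")
        if self.technical_cv < 0:
            raise DigeError("technical_cv must be >= 0")
        if self.n_differential > self.n_spots:
            raise DigeError("n_differential exceeds n_spots")
        if self.gain_range[0] <= 0 or self.gain_range[1] < self.gain_range[0]:
            raise DigeError("invalid gain range")
        if not 1 <= self.isoform_train_max:
            raise DigeError("isoform_train_max must be >= 1")
        if self.n_patients < 2:
            raise DigeError("need >= 2 patients")


def null_config(seed: int = 0, n_spots: int = 2000) -> SimulationConfig:
    """A no-signal configuration with independent spots.

    No planted effects, no marker loadings, no GFAP relation, singleton
    isoform trains and a single fraction: the setting for calibration checks
    (e.g. empirical type-I error) that presume independent null spots.
    """
    return SimulationConfig(
        n_spots=n_spots,
        n_differential=0,
        marker_panels=(),
        include_gfap=False,
        isoform_train_max=1,
        multi_train_prob=0.0,
        fractions=("cytosol",),
        seed=seed,
    )


@dataclass
class SyntheticTruth:
    """Ground-truth record emitted alongside a simulated study."""

    differential: pd.DataFrame              # fraction, spot_id, sign, lnfc
    marker_spots: dict[str, list[tuple[str, str]]]
    factors: pd.DataFrame                   # (patient, condition) x panel
    gliosis: pd.Series                      # per patient
    gfap_fc_lh: pd.Series                   # planted FC(L/H) per patient
    marker_loading: float                   # log10 loading on latent factors

    def differential_keys(self) -> set[tuple[str, str]]:
        return set(zip(self.differential["fraction"], self.differential["spot_id"]))

    def marker_labels(self) -> pd.Series:
        """(fraction, spot_id) -> panel name for every marker spot."""
        rows = {}
        for panel, spots in self.marker_spots.items():
            for key in spots:
                rows[key] = panel
        idx = pd.MultiIndex.from_tuples(rows.keys(), names=["fraction", "spot_id"])
        return pd.Series(list(rows.values()), index=idx, name="panel")

    def vascularity_ratio(self) -> pd.Series:
        """Per-patient high/low abundance ratio implied by the latent
        vascularity (erythrocyte) factor: the synthetic analogue of a
        stained blood-vessel length ratio."""
        if "erythrocyte" not in self.factors.columns:
            raise DigeError("no erythrocyte factor in this simulation")
        f = self.factors["erythrocyte"].unstack("condition")
        ratio = 10.0 ** (self.marker_loading * (f["high"] - f["low"]))
        ratio.name = "vascularity_ratio"
        return ratio

    def to_dict(self) -> dict:
        return {
            "differential": self.differential.to_dict(orient="records"),
            "marker_spots": {k: [list(t) for t in v]
                             for k, v in self.marker_spots.items()},
            "factors": {
                "|".join(map(str, k)): row.to_dict()
                for k, row in self.factors.iterrows()
            },
            "gliosis": self.gliosis.to_dict(),
            "gfap_fc_lh": self.gfap_fc_lh.to_dict(),
            "marker_loading": self.marker_loading,
        }


@dataclass
class SimulatedStudy:
    """Bundle of everything :func:`simulate_study` produces."""

    config: SimulationConfig
    design: StudyDesign
    tables: dict[str, SpotVolumeTable]
    metadata: PatientMetadata
    annotation: SpotAnnotation
    truth: SyntheticTruth
    gene_sets: GeneSetCollection


def _make_metadata(config: SimulationConfig, rng: np.random.Generator) -> PatientMetadata:
    if config.n_patients == 6:
        return default_cohort()
    rows = []
    for i in range(config.n_patients):
        low = int(rng.integers(0, 60))
        rows.append(
            {
                "gender": "F" if i % 2 else "M",
                "age": int(rng.integers(1, 40)),
                "spike_high": low + int(rng.integers(5, 300)),
                "spike_low": low,
                "histopathology": str(rng.choice(list(GLIOSIS_RATIO_BY_GRADE))),
            }
        )
    table = pd.DataFrame(
        rows, index=pd.Index([f"sim{i:02d}" for i in range(config.n_patients)],
                             name="patient_id")
    )
    return PatientMetadata(table=table)


def _make_design(config: SimulationConfig, patients) -> StudyDesign:
    gels = []
    for fraction in config.fractions:
        code = _FR_CODE.get(fraction, fraction[:2].upper())
        for p in patients:
            for rep, orientation in enumerate(("high", "low"), start=1):
                other = "low" if orientation == "high" else "high"
                gels.append(
                    GelRecord(
                        gel_id=f"{code}-{p}-r{rep}",
                        fraction=fraction,
                        patient_id=p,
                        channels={STANDARD_DYE: STANDARD_LABEL,
                                  "A": orientation, "B": other},
                    )
                )
    return StudyDesign(gels=gels)


def _draw_train_sizes(n_remaining: int, config: SimulationConfig,
                      rng: np.random.Generator) -> list[int]:
    sizes = []
    left = n_remaining
    while left > 0:
        if config.isoform_train_max > 1 and rng.random() < config.multi_train_prob:
            size = int(rng.integers(2, config.isoform_train_max + 1))
        else:
            size = 1
        size = min(size, left)
        sizes.append(size)
        left -= size
    return sizes


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate a full synthetic study (design, tables, truth).

    Measurement model per fraction: ``V(spot, gel, channel) =
    T(spot, sample) * G(image) * eps`` with ``eps`` log-normal at the
    configured CV, and ``T(spot, standard) = mean over the 2 n samples of
    T(spot, sample)`` (the pooled internal standard mixes every sample
    equally).  Deterministic given ``config.seed``.
    """
    root = np.random.SeedSequence(config.seed)
    global_ss, *fraction_ss = root.spawn(1 + len(config.fractions))
    rng_global = np.random.default_rng(global_ss)

    metadata = _make_metadata(config, rng_global)
    patients = metadata.patients
    samples = [(p, c) for p in patients for c in CONDITIONS]
    sample_cols = pd.MultiIndex.from_tuples(samples, names=["patient", "condition"])
    design = _make_design(config, patients)

    # latent per-sample factors, one per marker panel; the high-low offset
    # varies by patient so that factor-driven fold changes differ between
    # patients (as real vascularity differences would)
    factor_cols = [p.name for p in config.marker_panels]
    factors = pd.DataFrame(index=sample_cols, columns=factor_cols, dtype=float)
    for name in factor_cols:
        base = rng_global.normal(0.0, 1.0, size=len(patients))
        offset = rng_global.normal(0.75, 0.75, size=len(patients))
        for i, p in enumerate(patients):
            factors.loc[(p, "high"), name] = base[i] + offset[i] / 2.0
            factors.loc[(p, "low"), name] = base[i] - offset[i] / 2.0
    marker_loading = config.marker_snr * config.biological_sd

    gliosis = metadata.table["histopathology"].map(GLIOSIS_RATIO_BY_GRADE)
    gliosis.name = "gliosis"
    delta = metadata.delta_spike
    gfap_fc_lh = config.gfap_slope * delta + config.gfap_intercept
    gfap_fc_lh.name = "gfap_fc_lh"
    if config.include_gfap and (gfap_fc_lh <= 0).any():
        raise DigeError("planted GFAP FC(L/H) must be positive for all patients")

    n_samples = len(samples)
    high_idx = np.array([i for i, (_, c) in enumerate(samples) if c == "high"])
    low_idx = np.array([i for i, (_, c) in enumerate(samples) if c == "low"])
    patient_of = {p: i for i, p in enumerate(patients)}

    tables: dict[str, SpotVolumeTable] = {}
    ann_rows: list[dict] = []
    diff_rows: list[dict] = []
    marker_spots: dict[str, list[tuple[str, str]]] = {
        p.name: [] for p in config.marker_panels
    }
    nuclear_gfap_T: np.ndarray | None = None

    for fraction, ss in zip(config.fractions, fraction_ss):
        rng = np.random.default_rng(ss)
        code = _FR_CODE.get(fraction, fraction[:2].upper())
        spot_ids = [f"{code}-{i + 1:04d}" for i in range(config.n_spots)]

        # --- lay out special spots first, then ordinary isoform trains -----
        bound = max(
            config.n_spots,
            15 + 6 * sum(len(p.genes) for p in config.marker_panels)
            + config.n_differential,
        )
        gene: list[str | None] = [None] * bound
        group: list[str] = [""] * bound
        mw_class: list[str] = [""] * bound
        confidence: list[str] = ["unidentified"] * bound
        cursor = 0

        gfap_50k_rows: list[int] = []
        gfap_lmw_rows: list[int] = []
        gfap_cyt_rows: list[int] = []
        if config.include_gfap and fraction == "P1_nuclear":
            for _ in range(6):
                gfap_50k_rows.append(cursor)
                gene[cursor], group[cursor] = "GFAP", f"{code}:GFAP_50K"
                mw_class[cursor], confidence[cursor] = "GFAP_50kDa", "identified_ms"
                cursor += 1
            for _ in range(5):
                gfap_lmw_rows.append(cursor)
                gene[cursor], group[cursor] = "GFAP", f"{code}:GFAP_LMW"
                mw_class[cursor], confidence[cursor] = "GFAP_LMW", "identified_ms"
                cursor += 1
        if config.include_gfap and fraction == "cytosol":
            for _ in range(4):
                gfap_cyt_rows.append(cursor)
                gene[cursor], group[cursor] = "GFAP", f"{code}:GFAP_50K"
                mw_class[cursor], confidence[cursor] = "GFAP_50kDa", "identified_ms"
                cursor += 1

        panel_rows: dict[str, list[int]] = {}
        for panel in config.marker_panels:
            target = MARKER_FRACTIONS.get(panel.name, config.fractions[0])
            if target != fraction:
                continue
            rows = []
            for g in sorted(panel.genes):
                train = int(rng.integers(3, 7))
                for _ in range(train):
                    rows.append(cursor)
                    gene[cursor], group[cursor] = g, f"{code}:{g}"
                    confidence[cursor] = "identified_ms"
                    cursor += 1
            panel_rows[panel.name] = rows

        diff_rows_fraction: list[int] = []
        diff_signs = rng.choice([-1.0, 1.0], size=config.n_differential)
        counter = 0
        for _ in range(config.n_differential):
            diff_rows_fraction.append(cursor)
            counter += 1
            gene[cursor], group[cursor] = f"{code}D{counter:04d}", f"{code}:D{counter:04d}"
            confidence[cursor] = "identified_ms"
            cursor += 1

        if cursor > config.n_spots:
            raise DigeError(
                f"n_spots={config.n_spots} too small for the planted "
                f"markers/GFAP/differential spots ({cursor} needed)"
            )
        for name, rows in panel_rows.items():
            marker_spots[name].extend((fraction, spot_ids[r]) for r in rows)
        counter = 0
        for size in _draw_train_sizes(config.n_spots - cursor, config, rng):
            counter += 1
            conf = str(rng.choice(
                ["identified_ms", "inferred_single", "inferred_multiple",
                 "unidentified"],
                p=[0.5, 0.2, 0.15, 0.15],
            ))
            if size > 1 and conf == "unidentified":
                conf = "inferred_single"   # unidentified spots stay singletons
            g = f"{code}G{counter:04d}"
            for _ in range(size):
                group[cursor] = f"{code}:G{counter:04d}"
                if conf != "unidentified":
                    gene[cursor] = g
                confidence[cursor] = conf
                cursor += 1

        gene = gene[: config.n_spots]
        group = group[: config.n_spots]
        mw_class = mw_class[: config.n_spots]
        confidence = confidence[: config.n_spots]

        # --- true abundances ----------------------------------------------
        base = rng.normal(config.baseline_log10_mean, config.baseline_log10_sd,
                          size=config.n_spots)
        group_ids = pd.Series(group)
        group_codes, _ = pd.factorize(group_ids)
        group_sizes = np.bincount(group_codes)
        shared = rng.normal(0.0, 1.0, size=(group_sizes.size, n_samples))
        own = rng.normal(0.0, 1.0, size=(config.n_spots, n_samples))
        rho = config.isoform_correlation
        multi = group_sizes[group_codes] > 1
        eff = np.where(
            multi[:, None],
            math.sqrt(rho) * shared[group_codes] + math.sqrt(1 - rho) * own,
            own,
        ) * config.biological_sd

        for name, rows in panel_rows.items():
            f = factors[name].to_numpy(dtype=float)
            eff[rows, :] += marker_loading * f[None, :]

        half = config.differential_lnfc / math.log(10.0) / 2.0
        for r, sign in zip(diff_rows_fraction, diff_signs):
            eff[r, high_idx] += sign * half
            eff[r, low_idx] -= sign * half
            diff_rows.append(
                {
                    "fraction": fraction,
                    "spot_id": spot_ids[r],
                    "sign": int(sign),
                    "lnfc": float(sign * config.differential_lnfc),
                }
            )

        if gfap_50k_rows:
            # full-length GFAP is one of the most abundant gel proteins
            base[gfap_50k_rows] = (config.baseline_log10_mean + 1.0
                                   + 0.1 * rng.standard_normal(len(gfap_50k_rows)))
            # exact planted relation; biological noise suppressed on these
            # spots so the realized FC(L/H) stays strictly monotone in
            # delta-spike (the property the generator guarantees)
            eff[gfap_50k_rows, :] = 0.0
            shift = np.zeros(n_samples)
            for (p, c), i in zip(samples, range(n_samples)):
                s = math.log10(gfap_fc_lh[p]) / 2.0
                if config.gfap_jitter > 0:
                    s += rng.normal(0.0, config.gfap_jitter)
                shift[i] = s if c == "low" else -s
            eff[gfap_50k_rows, :] += shift[None, :]
        if gfap_lmw_rows:
            # 38-40 kDa cleavage fragments: much fainter than the full-length
            # train, and co-varying with the blood compartment
            base[gfap_lmw_rows] = (config.baseline_log10_mean - 0.7
                                   + 0.1 * rng.standard_normal(len(gfap_lmw_rows)))
            if "erythrocyte" in factors.columns:
                f = factors["erythrocyte"].to_numpy(dtype=float)
                eff[gfap_lmw_rows, :] += marker_loading * f[None, :]

        T = 10.0 ** (base[:, None] + eff)

        if gfap_cyt_rows:
            if nuclear_gfap_T is not None:
                target_total = nuclear_gfap_T.sum(axis=0)  # per sample, 11 spots
                for i, (p, _) in enumerate(samples):
                    scale = gliosis[p] * target_total[i] / T[gfap_cyt_rows, i].sum()
                    T[gfap_cyt_rows, i] *= scale
        if gfap_50k_rows:
            nuclear_gfap_T = T[gfap_50k_rows + gfap_lmw_rows, :]

        # --- measurement: pooled standard, gains, technical noise ----------
        std = T.mean(axis=1)
        sigma = (math.sqrt(math.log(1.0 + config.technical_cv ** 2))
                 if config.technical_cv > 0 else 0.0)
        columns = []
        values = []
        for gel in design.gels_for(fraction):
            for dye in (STANDARD_DYE,) + SAMPLE_DYES:
                sample = design.sample_of(gel.gel_id, dye)
                true = std if sample is None else T[:, 2 * patient_of[sample[0]]
                                                   + CONDITIONS.index(sample[1])]
                gain = (1.0 if config.gain_range == (1.0, 1.0)
                        else float(rng.uniform(*config.gain_range)))
                eps = (np.exp(rng.normal(-sigma ** 2 / 2.0, sigma,
                                         size=config.n_spots))
                       if sigma > 0 else 1.0)
                columns.append((gel.gel_id, dye))
                values.append(true * gain * eps)
        vol = pd.DataFrame(
            np.column_stack(values),
            index=pd.Index(spot_ids, name="spot_id"),
            columns=pd.MultiIndex.from_tuples(columns, names=["gel_id", "dye"]),
        )
        tables[fraction] = SpotVolumeTable(fraction=fraction, volumes=vol)

        for i, sid in enumerate(spot_ids):
            ann_rows.append(
                {
                    "fraction": fraction,
                    "spot_id": sid,
                    "gene_symbol": gene[i],
                    "confidence": confidence[i],
                    "isoform_group": group[i],
                    "mw_class": mw_class[i] or None,
                }
            )

    annotation = SpotAnnotation(table=pd.DataFrame(ann_rows))
    truth = SyntheticTruth(
        differential=pd.DataFrame(
            diff_rows, columns=["fraction", "spot_id", "sign", "lnfc"]
        ),
        marker_spots=marker_spots,
        factors=factors,
        gliosis=gliosis,
        gfap_fc_lh=gfap_fc_lh,
        marker_loading=marker_loading,
    )
    gene_sets = _make_gene_sets(annotation, truth, rng_global, config)
    return SimulatedStudy(config=config, design=design, tables=tables,
                          metadata=metadata, annotation=annotation,
                          truth=truth, gene_sets=gene_sets)


def _make_gene_sets(annotation: SpotAnnotation, truth: SyntheticTruth,
                    rng: np.random.Generator, config: SimulationConfig,
                    n_decoys: int = 8, decoy_size: int = 20) -> GeneSetCollection:
    """Gene sets for the enrichment stage: one set per marker panel, one set
    of the planted differential genes, and random decoy sets."""
    universe = sorted(annotation.genes())
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for panel in config.marker_panels:
        if not panel.genes & set(universe):
            continue  # panel's fraction was not simulated
        sets[f"PANEL_{panel.name.upper()}"] = panel.genes
        descriptions[f"PANEL_{panel.name.upper()}"] = f"{panel.name} marker panel"
    gene_of = annotation.gene_of()
    diff_genes = {
        gene_of.get((f, s))
        for f, s in truth.differential_keys()
        if isinstance(gene_of.get((f, s)), str)
    }
    if diff_genes:
        sets["DIFFERENTIAL_RESPONSE"] = frozenset(diff_genes)
        descriptions["DIFFERENTIAL_RESPONSE"] = "genes of planted differential spots"
    background = [g for g in universe if g not in diff_genes]
    size = min(decoy_size, len(background))
    if size > 0:
        for i in range(n_decoys):
            members = rng.choice(background, size=size, replace=False)
            sets[f"DECOY_{i + 1:02d}"] = frozenset(members)
            descriptions[f"DECOY_{i + 1:02d}"] = "random decoy set"
    return GeneSetCollection(sets=sets, universe=frozenset(universe),
                             descriptions=descriptions)


def truth_recovery_report(
    truth: SyntheticTruth,
    differential: pd.DataFrame,
    assignment: pd.Series | None = None,
) -> dict:
    """Score downstream results against the planted truth.

    ``differential`` is a (concatenated) differential table with a
    ``fraction`` column and spot-id index.  Returns sensitivity/FDR of both
    the significance call and the SOI set versus the planted differential
    spots, the overall called fraction, and -- when a clustering
    ``assignment`` over (fraction, spot_id) is supplied -- the adjusted Rand
    index of the cut clusters against the planted marker-panel memberships.
    """
    from sklearn.metrics import adjusted_rand_score

    keys = set(zip(differential["fraction"], differential.index))
    planted = truth.differential_keys()
    if not planted <= keys:
        raise DigeError("differential table does not cover the planted spots")

    def _rates(flag: str) -> tuple[float, float]:
        called = set(zip(differential.loc[differential[flag], "fraction"],
                         differential.index[differential[flag]]))
        tp = len(called & planted)
        sens = tp / len(planted) if planted else math.nan
        fdr = (len(called) - tp) / len(called) if called else 0.0
        return sens, fdr

    sens_sig, fdr_sig = _rates("significant")
    sens_soi, fdr_soi = _rates("soi")
    report = {
        "n_spots": int(len(differential)),
        "n_planted": int(len(planted)),
        "significant_fraction": float(differential["significant"].mean()),
        "sensitivity_significant": sens_sig,
        "fdr_significant": fdr_sig,
        "sensitivity_soi": sens_soi,
        "fdr_soi": fdr_soi,
    }
    if assignment is not None:
        labels = truth.marker_labels()
        common = labels.index.intersection(assignment.index)
        if len(common) == 0:
            raise DigeError("assignment shares no spots with the planted markers")
        report["marker_ari"] = float(
            adjusted_rand_score(labels.loc[common], assignment.loc[common])
        )
        report["n_marker_spots"] = int(len(common))
    return report
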