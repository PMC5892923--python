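"""End-to-end orchestration: simulate -> normalize -> test -> SOI ->
cluster -> roll-up -> enrich, with a JSON run manifest.

Each stage writes plain-text artifacts (TSV/JSON/YAML/GMT/Newick) into the
output directory; the manifest records package and library versions, the
seed, a hash of the configuration and per-stage wall times, so a run can be
audited and reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import sklearn
import yaml

from . import __version__
from .clustering import (
    DEFAULT_K,
    WARD_D2,
    cluster_profiles,
    correlate_cluster_with_external,
    linkage_to_newick,
    loocv_stability,
    marker_cluster_score,
)
from .differential import build_soi_set, differential_table
from .enrich import (
    DEFAULT_FC_ENRICH,
    DEFAULT_LOGP_MIN,
    DEFAULT_MIN_PATIENTS,
    cross_patient_comparison,
    enrich_all,
    erythrocyte_excluded_genes,
    per_patient_lists,
)
from .io import (
    DigeError,
    write_annotation,
    write_design,
    write_gmt,
    write_patient_table,
    write_spot_table,
)
from .normalize import (
    ExpressionMatrix,
    average_replicates,
    ratiometric_normalize,
    total_volume_normalize,
    unite_fractions,
)
from .rollup import (
    aggregate_isoforms,
    correlate_fc_with_spike,
    fraction_ratio,
    paired_total_test,
)
from .simulate import SimulatedStudy, SimulationConfig, simulate_study, truth_recovery_report


@dataclass
class RunConfig:
    """Thresholds and stage settings for a full pipeline run."""

    outdir: Path
    seed: int = 0
    alpha: float = 0.05
    fc_min: float = 1.25
    fc_enrich: float = DEFAULT_FC_ENRICH
    k: int = DEFAULT_K
    logp_min: float = DEFAULT_LOGP_MIN
    min_patients: int = DEFAULT_MIN_PATIENTS
    min_markers: int = 2
    anova_gate: bool = False
    bh_correct: bool = False
    ward_variant: str = WARD_D2
    run_loocv: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        for name in ("alpha", "fc_min", "fc_enrich", "logp_min"):
            if getattr(self, name) < 0:
                raise DigeError(f"threshold {name} must be non-negative")
        if self.k < 1:
            raise DigeError("k must be >= 1")
        # the run seed overrides the simulation seed so one flag controls all
        self.sim = dataclasses.replace(self.sim, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path, outdir: str | Path,
                  seed: int | None = None) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**payload.pop("sim", {}))
        if seed is not None:
            payload["seed"] = seed
        return cls(outdir=Path(outdir), sim=sim, **payload)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def pattern_profiles(united: ExpressionMatrix, keys=None) -> pd.DataFrame:
    """Expression-pattern profiles for clustering.

    log10 abundance centred per spot, i.e. each spot's level and direction
    of variation relative to its across-sample mean -- which, by the pooled
    standard's construction, is the spot's internal-standard level.
    """
    data = np.log10(united.data)
    data = data.sub(data.mean(axis=1), axis=0)
    if keys is not None:
        data = data.loc[keys]
    return data


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a simulated study and write all artifacts.

    Returns a dict of in-memory stage results (also all serialized under
    ``config.outdir``).  Deterministic given the seed and configuration.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    results: dict = {}

    def stage(name):
        class _T:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, *exc):
                timings[name] = round(time.perf_counter() - self_inner.t0, 3)
                return False

        return _T()

    try:
        with stage("simulate"):
            study = simulate_study(config.sim)
            _write_study(study, out)
        results["study"] = study

        with stage("normalize_and_test"):
            diff_tables = []
            tv_matrices = []
            for fraction, table in study.tables.items():
                ratio = ratiometric_normalize(table, study.design)
                expr_ratio = average_replicates(ratio, study.design)
                tv = total_volume_normalize(table, study.design)
                expr_tv = average_replicates(tv, study.design)
                tv_matrices.append(expr_tv)
                diff = differential_table(
                    ratio, expr_ratio, alpha=config.alpha, fc_min=config.fc_min,
                    anova_gate=config.anova_gate, bh_correct=config.bh_correct,
                )
                diff.to_csv(out / f"differential_{fraction}.tsv", sep="\t")
                diff_tables.append(diff)
            united = unite_fractions(tv_matrices)
        results["differential"] = pd.concat(diff_tables)
        results["united"] = united

        with stage("select_soi"):
            soi = build_soi_set(diff_tables)
            soi.to_csv(out / "soi.tsv", sep="\t")
        results["soi"] = soi

        with stage("cluster"):
            soi_keys = pd.MultiIndex.from_frame(
                soi.reset_index()[["fraction", "spot_id"]]
            )
            cluster = None
            if len(soi_keys) >= max(2, config.k):
                profiles = pattern_profiles(united, keys=soi_keys)
                cluster = cluster_profiles(profiles, k=config.k,
                                           variant=config.ward_variant)
                if config.run_loocv:
                    cluster.stability = loocv_stability(
                        profiles, k=config.k, variant=config.ward_variant
                    )
                hl = united.hl_ratio().loc[soi_keys]
                labels, scores = marker_cluster_score(
                    cluster.assignment, study.annotation,
                    hl_ratios=hl, min_markers=config.min_markers,
                )
                cluster.labels = labels
                cluster.assignment.to_csv(out / "cluster_assignment.tsv", sep="\t")
                if cluster.stability is not None:
                    cluster.stability.rename_axis("cluster").to_csv(
                        out / "cluster_stability.tsv", sep="\t"
                    )
                scores.to_csv(out / "cluster_scores.tsv", sep="\t")
                (out / "cluster_tree.newick").write_text(
                    linkage_to_newick(
                        cluster.linkage,
                        ["|".join(k) for k in profiles.index],
                    )
                    + "\n"
                )
                (out / "cluster_labels.json").write_text(
                    json.dumps({str(k): v for k, v in labels.items()}, indent=2)
                    + "\n"
                )
                results["cluster"] = cluster
                results["cluster_scores"] = scores

        with stage("vascularity"):
            vasc = _vascularity_report(config, study, results)
            if vasc:
                (out / "vascularity_report.json").write_text(
                    json.dumps(_jsonable(vasc), indent=2) + "\n"
                )
                results["vascularity"] = vasc

        with stage("rollup"):
            gfap = _gfap_report(study, united)
            if gfap:
                (out / "gfap_report.json").write_text(
                    json.dumps(_jsonable(gfap), indent=2) + "\n"
                )
                results["gfap"] = gfap

        with stage("enrich"):
            excluded = set()
            if results.get("cluster") is not None:
                excluded = erythrocyte_excluded_genes(
                    results["cluster"].assignment, results["cluster"].labels,
                    study.annotation,
                )
            lists = per_patient_lists(soi, study.annotation,
                                      fc_cutoff=config.fc_enrich,
                                      excluded_genes=excluded)
            records = enrich_all(lists, study.gene_sets)
            records.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            recurrent = cross_patient_comparison(
                records, logp_min=config.logp_min,
                min_patients=config.min_patients,
            )
            recurrent.to_csv(out / "recurrent_sets.tsv", sep="\t")
            results["enrichment"] = records
            results["recurrent"] = recurrent

        with stage("truth_recovery"):
            assignment = (results["cluster"].assignment
                          if results.get("cluster") is not None else None)
            recovery = truth_recovery_report(
                study.truth, results["differential"], assignment=assignment
            )
            (out / "truth_recovery.json").write_text(
                json.dumps(_jsonable(recovery), indent=2) + "\n"
            )
            results["recovery"] = recovery
    except DigeError as exc:
        raise DigeError(f"pipeline stage {list(timings)[-1] if timings else '?'} "
                        f"failed: {exc}") from exc

    manifest = {
        "digepipe": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "sklearn": sklearn.__version__,
        "seed": config.seed,
        "config": _jsonable(config),
        "config_sha256": hashlib.sha256(
            json.dumps(_jsonable(config), sort_keys=True).encode()
        ).hexdigest(),
        "timings_s": timings,
        "artifacts": sorted(
            {p.name for p in out.iterdir() if p.is_file()} | {"manifest.json"}
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    results["manifest"] = manifest
    return results


def _write_study(study: SimulatedStudy, out: Path) -> None:
    write_design(study.design, out / "design.yaml")
    write_patient_table(study.metadata, out / "metadata.tsv")
    write_annotation(study.annotation, out / "annotation.tsv")
    write_gmt(study.gene_sets, out / "gene_sets.gmt")
    for fraction, table in study.tables.items():
        write_spot_table(table, out / f"spot_table_{fraction}.tsv")
    (out / "truth.json").write_text(
        json.dumps(_jsonable(study.truth.to_dict()), indent=2) + "\n"
    )


def _vascularity_report(config: RunConfig, study: SimulatedStudy,
                        results: dict) -> dict | None:
    """Correlate the erythrocyte-cluster score with the latent vascularity
    ratio (the synthetic analogue of stained vessel-length ratios)."""
    cluster = results.get("cluster")
    if cluster is None or not study.truth.marker_spots.get("erythrocyte"):
        return None
    ery = [c for c, name in cluster.labels.items() if name == "erythrocyte"]
    if not ery:
        return None
    scores = results["cluster_scores"]
    # combine member clusters by their median score per patient
    score = scores.loc[ery].median(axis=0)
    try:
        r, p = correlate_cluster_with_external(
            score, study.truth.vascularity_ratio()
        )
    except DigeError:
        return None
    return {
        "erythrocyte_clusters": ery,
        "n_spots": int((cluster.assignment.isin(ery)).sum()),
        "score_per_patient": score.to_dict(),
        "pearson_r": r,
        "pearson_p": p,
    }


def _gfap_report(study: SimulatedStudy, united: ExpressionMatrix) -> dict | None:
    """GFAP roll-up: totals, paired tests, solubility ratio, spike relation."""
    ann = study.annotation
    nuc_all = ann.spots_for_gene("GFAP", fraction="P1_nuclear")
    nuc_50k = ann.spots_for_gene("GFAP", fraction="P1_nuclear",
                                 mw_class="GFAP_50kDa")
    if len(nuc_all) == 0 or len(nuc_50k) == 0:
        return None
    nuclear = ExpressionMatrix(
        data=united.data.xs("P1_nuclear", level="fraction"),
        mode=united.mode, fraction="P1_nuclear",
    )
    total_all = aggregate_isoforms(nuclear, nuc_all, "GFAP")
    total_50k = aggregate_isoforms(nuclear, nuc_50k, "GFAP")
    test_all = paired_total_test(total_all)
    test_50k = paired_total_test(total_50k)
    report = {
        "n_spots_all": len(nuc_all),
        "n_spots_50k": len(nuc_50k),
        "paired_p_all": test_all.p,
        "fc_all_lh": test_all.fc_lh,
        "paired_p_50k": test_50k.p,
        "fc_50k_lh": test_50k.fc_lh,
    }
    corr = correlate_fc_with_spike(total_50k.fold_change("LH"), study.metadata)
    report["spike_correlation"] = {
        "pearson_r": corr.r, "pearson_p": corr.p,
        "slope": corr.slope, "intercept": corr.intercept,
        "kendall_tau": corr.tau, "kendall_p": corr.tau_p, "n": corr.n,
    }
    cyt_spots = ann.spots_for_gene("GFAP", fraction="cytosol")
    if cyt_spots and "cytosol" in study.tables:
        cyt = ExpressionMatrix(
            data=united.data.xs("cytosol", level="fraction"),
            mode=united.mode, fraction="cytosol",
        )
        total_cyt = aggregate_isoforms(cyt, cyt_spots, "GFAP")
        ratio = fraction_ratio(total_cyt, total_all)
        report["cyt_nuc_ratio"] = {
            p: {c: float(ratio.loc[p, c]) for c in ratio.columns}
            for p in ratio.index
        }
    return report
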