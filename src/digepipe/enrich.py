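"""Gene-set over-representation and cross-patient recurrence.

For each patient, the genes behind that patient's strongly changing spots
of interest (|fold change| >= 1.3 by default) are tested against every gene
set with the one-sided Fisher exact test (hypergeometric upper tail) over a
finite background universe.  Because erythrocyte-panel proteins reflect
vascularity rather than a molecular pathway, genes whose SOIs all sit in
erythrocyte-labelled clusters are excluded from the lists.

A set counts as *recurrent* when its -log10 p reaches a threshold (1.3,
i.e. p <= 0.05) in at least ``min_patients`` patients; recurrent sets are
ranked by the summed -log10 p over all patients, with the per-patient
contributions retained (stacked-bar semantics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .io import DigeError, GeneSetCollection, SpotAnnotation

DEFAULT_FC_ENRICH = 1.3
DEFAULT_LOGP_MIN = 1.3
DEFAULT_MIN_PATIENTS = 3


@dataclass
class EnrichmentRecord:
    """One (patient, gene set) over-representation test."""

    patient_id: str
    set_name: str
    overlap: int
    list_size: int
    set_size: int
    universe_size: int
    p: float

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.p)


def fisher_enrichment(
    gene_list, gene_set, universe, patient_id: str = "", set_name: str = ""
) -> EnrichmentRecord:
    """One-sided Fisher exact (hypergeometric upper tail) enrichment test.

    ``p = P(X >= overlap)`` for X hypergeometric with the universe as
    population, the gene set as successes and the list size as draws.
    Symbols are upper-cased and restricted to the universe; duplicates and
    ordering are irrelevant.
    """
    universe = {g.upper() for g in universe}
    if not universe:
        raise DigeError("empty universe")
    gene_list = {g.upper() for g in gene_list} & universe
    gene_set = {g.upper() for g in gene_set} & universe
    if not gene_list:
        raise DigeError("empty gene list (after harmonization with the universe)")
    k = len(gene_list & gene_set)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(gene_set), len(gene_list)))
    return EnrichmentRecord(patient_id=patient_id, set_name=set_name, overlap=k,
                            list_size=len(gene_list), set_size=len(gene_set),
                            universe_size=len(universe), p=min(p, 1.0))


def erythrocyte_excluded_genes(
    assignment: pd.Series,
    labels: dict[int, str],
    annotation: SpotAnnotation,
    panel_name: str = "erythrocyte",
) -> set[str]:
    """Genes whose every clustered SOI lies in an erythrocyte-labelled cluster.

    A gene also expressed outside that cluster stays in the analysis.
    """
    ery_clusters = {c for c, name in labels.items() if name == panel_name}
    if not ery_clusters:
        return set()
    gene_of = annotation.gene_of()
    genes = gene_of.reindex(assignment.index).dropna()
    inside = set(genes[assignment.loc[genes.index].isin(ery_clusters)])
    outside = set(genes[~assignment.loc[genes.index].isin(ery_clusters)])
    return inside - outside


def per_patient_lists(
    soi_table: pd.DataFrame,
    annotation: SpotAnnotation,
    fc_cutoff: float = DEFAULT_FC_ENRICH,
    excluded_genes=(),
) -> dict[str, set[str]]:
    """Per-patient gene lists from SOIs with |signed FC| >= cutoff.

    ``soi_table`` is a differential/SOI table with a ``fraction`` column and
    per-patient ``fc_<patient>`` columns.  Unidentified spots contribute
    nothing; ``excluded_genes`` (e.g. erythrocyte-cluster genes) are
    removed from every list.
    """
    excluded = {g.upper() for g in excluded_genes}
    gene_of = annotation.gene_of()
    keys = pd.MultiIndex.from_frame(
        soi_table.reset_index()[["fraction", "spot_id"]]
    )
    genes = gene_of.reindex(keys)
    fc_cols = [c for c in soi_table.columns if c.startswith("fc_")]
    lists: dict[str, set[str]] = {}
    for col in fc_cols:
        patient = col[3:]
        hit = (soi_table[col].abs() >= fc_cutoff).to_numpy()
        symbols = set(genes.to_numpy()[hit])
        symbols = {g for g in symbols if isinstance(g, str)} - excluded
        lists[patient] = symbols
    return lists


def enrich_all(
    lists: dict[str, set[str]],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Fisher enrichment of every patient list against every gene set."""
    rows = []
    for patient, genes in lists.items():
        for name, members in collection.sets.items():
            if not genes:
                continue
            rec = fisher_enrichment(genes, members, collection.universe,
                                    patient_id=patient, set_name=name)
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "set_name": rec.set_name,
                    "overlap": rec.overlap,
                    "list_size": rec.list_size,
                    "set_size": rec.set_size,
                    "universe_size": rec.universe_size,
                    "p": rec.p,
                    "neg_log10_p": rec.neg_log10_p,
                }
            )
    return pd.DataFrame(rows)


def cross_patient_comparison(
    records: pd.DataFrame,
    logp_min: float = DEFAULT_LOGP_MIN,
    min_patients: int = DEFAULT_MIN_PATIENTS,
) -> pd.DataFrame:
    """Recurrently enriched sets, ranked by summed -log10 p.

    A set qualifies when its -log10 p >= ``logp_min`` in at least
    ``min_patients`` patients.  The returned frame has one row per
    qualifying set: per-patient -log10 p columns, the number of qualifying
    patients, and the total score used for ranking (descending).
    """
    if records.empty:
        return pd.DataFrame(columns=["n_qualifying", "score"])
    wide = records.pivot_table(index="set_name", columns="patient_id",
                               values="neg_log10_p", fill_value=0.0)
    qualifying = (wide >= logp_min).sum(axis=1)
    keep = wide[qualifying >= min_patients].copy()
    keep["n_qualifying"] = qualifying[keep.index]
    keep["score"] = wide.loc[keep.index].sum(axis=1)
    return keep.sort_values("score", ascending=False)
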