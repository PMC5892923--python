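"""Per-patient screening, the cross-patient paired test, and SOI selection.

The study design is paired within patient (high- vs low-spiking tissue from
the same brain) with dye-swap technical replicates nested inside each
patient.  Each gel yields one technical ln fold-change ln(H/L) per spot;
averaging a patient's replicate ln FCs and testing the patient means against
zero with a one-sample two-sided t-test (df = n_patients - 1) is the exact
likelihood analysis of the balanced random-intercept-per-patient model, and
is what :func:`cross_patient_test` computes.

Fold changes are reported in the signed convention used throughout gel
proteomics: +H/L when the high-spiking sample is at least as abundant,
-L/H otherwise, so |FC| >= 1 always and the sign carries the direction.

Spots of interest (SOIs) are the union of spots that pass the cross-patient
test (p < alpha and |FC| >= fc_min) and "variable" spots whose per-patient
fold change exceeds the threshold in at least half of the patients.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import DigeError
from .normalize import ExpressionMatrix

DEFAULT_ALPHA = 0.05
DEFAULT_FC_MIN = 1.25


@dataclass
class CrossPatientResult:
    """Outcome of the nested paired test for one spot."""

    t: float
    df: int
    p: float
    mean_lnfc: float
    fc: float          # signed geometric-mean fold change
    degenerate: bool = False


@dataclass
class DifferentialRecord:
    """One spot's differential-analysis summary (a row of the table API)."""

    spot_id: str
    fraction: str
    patient_fc: dict[str, float]
    patient_screen: dict[str, bool]
    mean_lnfc: float
    t: float
    df: int
    p: float
    fc: float
    significant: bool
    variable: bool
    soi: bool


def signed_fold_change(h, l):
    """Signed fold change: +h/l if h >= l else -l/h.  |result| >= 1 always."""
    h = np.asarray(h, dtype=float)
    l = np.asarray(l, dtype=float)
    if (h <= 0).any() or (l <= 0).any():
        raise DigeError("fold change requires strictly positive abundances")
    out = np.where(h >= l, h / l, -l / h)
    return float(out) if out.ndim == 0 else out


def signed_fc_from_lnfc(mean_lnfc):
    """Signed-FC convention applied to a mean ln(H/L): sign(x) * exp(|x|)."""
    x = np.asarray(mean_lnfc, dtype=float)
    out = np.where(x >= 0, np.exp(x), -np.exp(-x))
    return float(out) if out.ndim == 0 else out


def lnfc_by_gel(channels: pd.DataFrame) -> pd.DataFrame:
    """Per-gel technical ln(high/low) fold changes.

    ``channels`` carries ``(patient, condition, gel_id)`` columns (one high
    and one low channel per gel).  Returns spots x (patient, gel_id).
    """
    cols = channels.columns
    gels = sorted(set(zip(cols.get_level_values("patient"),
                          cols.get_level_values("gel_id"))))
    out = {}
    for patient, gel in gels:
        h = channels[(patient, "high", gel)].to_numpy()
        l = channels[(patient, "low", gel)].to_numpy()
        out[(patient, gel)] = np.log(h) - np.log(l)
    frame = pd.DataFrame(out, index=channels.index)
    frame.columns.names = ["patient", "gel_id"]
    return frame


def cross_patient_test(lnfc_by_patient) -> CrossPatientResult:
    """Random-intercept-per-patient test of mean ln FC against zero.

    ``lnfc_by_patient`` maps patient -> sequence of technical-replicate
    ln(H/L) values.  For the balanced dye-swap design this reduces exactly to
    a one-sample two-sided t-test on the per-patient replicate means with
    df = n_patients - 1.  A zero variance across patient means leaves p
    undefined and is flagged degenerate.
    """
    means = np.array([float(np.mean(v)) for v in dict(lnfc_by_patient).values()])
    n = means.size
    if n < 2:
        raise DigeError("cross-patient test requires >= 2 patients")
    mean = float(means.mean())
    sd = float(means.std(ddof=1))
    if sd <= abs(mean) * 1e-10:   # zero variance up to float rounding
        return CrossPatientResult(t=math.nan, df=n - 1, p=math.nan,
                                  mean_lnfc=mean, fc=signed_fc_from_lnfc(mean),
                                  degenerate=True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return CrossPatientResult(t=t, df=n - 1, p=float(p), mean_lnfc=mean,
                              fc=signed_fc_from_lnfc(mean))


def cross_patient_table(lnfc: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`cross_patient_test` over all spots.

    ``lnfc`` is spots x (patient, gel) as from :func:`lnfc_by_gel`.  Returns
    a frame with columns ``mean_lnfc, t, df, p, fc, degenerate``.
    """
    means = lnfc.T.groupby(level="patient").mean().T.to_numpy()
    n = means.shape[1]
    if n < 2:
        raise DigeError("cross-patient test requires >= 2 patients")
    mean = means.mean(axis=1)
    sd = means.std(axis=1, ddof=1)
    degenerate = sd <= np.abs(mean) * 1e-10
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[degenerate] = np.nan
    t[degenerate] = np.nan
    return pd.DataFrame(
        {
            "mean_lnfc": mean,
            "t": t,
            "df": n - 1,
            "p": p,
            "fc": signed_fc_from_lnfc(mean),
            "degenerate": degenerate,
        },
        index=lnfc.index,
    )


def per_patient_screen(
    channels: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    fc_min: float = DEFAULT_FC_MIN,
    anova_gate: bool = False,
) -> pd.DataFrame:
    """Per-(spot, patient) expression-difference call on replicate channels.

    The call is ``|signed FC of replicate means| >= fc_min``; with
    ``anova_gate`` a one-way ANOVA on the log abundances of the high vs low
    replicate channels (equivalent to the squared two-sample t with two
    groups) must additionally reach ``p < alpha``.  If either condition has
    fewer than two replicate channels the gate is skipped with a warning and
    the call falls back to the fold-change criterion.
    """
    patients = list(channels.columns.get_level_values("patient").unique())
    calls = {}
    for patient in patients:
        h = channels[patient]["high"]
        l = channels[patient]["low"]
        fc = signed_fold_change(h.mean(axis=1), l.mean(axis=1))
        call = np.abs(fc) >= fc_min
        if anova_gate:
            if h.shape[1] < 2 or l.shape[1] < 2:
                warnings.warn(
                    f"patient {patient!r}: fewer than 2 replicates per condition; "
                    "ANOVA gate skipped (fold-change-only screen)",
                    stacklevel=2,
                )
            else:
                res = stats.ttest_ind(np.log(h.to_numpy()), np.log(l.to_numpy()),
                                      axis=1)
                call = call & (res.pvalue < alpha)
        calls[patient] = call
    return pd.DataFrame(calls, index=channels.index)


def patient_fold_changes(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-patient signed FC from replicate-averaged abundances."""
    out = {}
    for p in expr.patients:
        out[p] = signed_fold_change(expr.sample(p, "high"), expr.sample(p, "low"))
    return pd.DataFrame(out, index=expr.data.index)


def call_significant(p, fc, alpha: float = DEFAULT_ALPHA,
                     fc_min: float = DEFAULT_FC_MIN):
    """Significance per the headline rule: p < alpha and |FC| >= fc_min.

    No multiple-testing correction is applied here; Benjamini-Hochberg is
    available through :func:`differential_table`.
    """
    p = np.asarray(p, dtype=float)
    fc = np.asarray(fc, dtype=float)
    out = (p < alpha) & (np.abs(fc) >= fc_min)
    out = out & ~np.isnan(p)
    return bool(out) if out.ndim == 0 else out


def select_variable(screen: pd.DataFrame, min_patients: int | None = None) -> pd.Series:
    """Variable-spot rule: screened positive in at least ``min_patients``.

    Defaults to at least half of the patients (ceil(n/2); 3 of 6).
    """
    n = screen.shape[1]
    if min_patients is None:
        min_patients = math.ceil(n / 2)
    out = screen.sum(axis=1) >= min_patients
    out.name = "variable"
    return out


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    return stats.false_discovery_control(p, method="bh")


def differential_table(
    channels: pd.DataFrame,
    expr: ExpressionMatrix,
    alpha: float = DEFAULT_ALPHA,
    fc_min: float = DEFAULT_FC_MIN,
    min_patients: int | None = None,
    anova_gate: bool = False,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Full differential analysis of one fraction.

    Combines the cross-patient nested test (on per-gel ln FC replicates),
    the per-patient screen, per-patient signed fold changes from the
    replicate-averaged matrix, and the significant/variable/SOI flags into a
    single spots-indexed frame.  ``bh_correct`` replaces raw p-values with
    Benjamini-Hochberg adjusted ones before the significance call.
    """
    lnfc = lnfc_by_gel(channels)
    table = cross_patient_table(lnfc)
    if bh_correct:
        ok = ~table["p"].isna()
        adj = table["p"].copy()
        adj[ok] = benjamini_hochberg(table.loc[ok, "p"].to_numpy())
        table["p"] = adj
    screen = per_patient_screen(channels, alpha=alpha, fc_min=fc_min,
                                anova_gate=anova_gate)
    pfc = patient_fold_changes(expr)
    table = table.join(pfc.add_prefix("fc_"))
    table = table.join(screen.add_prefix("screen_"))
    table["significant"] = call_significant(table["p"], table["fc"],
                                            alpha=alpha, fc_min=fc_min)
    table["variable"] = select_variable(screen, min_patients=min_patients)
    table["soi"] = table["significant"] | table["variable"]
    table.insert(0, "fraction", expr.fraction)
    table.index.name = "spot_id"
    return table


def build_soi_set(tables) -> pd.DataFrame:
    """Union of SOI rows across fractions, provenance flags kept.

    Fractions stay distinct: the same protein may legitimately appear as a
    spot of interest in more than one subcellular fraction.  Accepts any
    iterable of per-fraction differential tables (possibly empty).
    """
    tables = [t for t in tables if len(t)]
    if not tables:
        return pd.DataFrame(
            columns=["fraction", "significant", "variable", "soi"]
        ).rename_axis("spot_id")
    combined = pd.concat(tables, axis=0)
    return combined[combined["soi"]].copy()


def records_from_table(table: pd.DataFrame) -> list[DifferentialRecord]:
    """Materialize :class:`DifferentialRecord` objects from a table."""
    fc_cols = [c for c in table.columns if c.startswith("fc_")]
    screen_cols = [c for c in table.columns if c.startswith("screen_")]
    records = []
    for spot_id, row in table.iterrows():
        records.append(
            DifferentialRecord(
                spot_id=str(spot_id),
                fraction=row["fraction"],
                patient_fc={c[3:]: row[c] for c in fc_cols},
                patient_screen={c[7:]: bool(row[c]) for c in screen_cols},
                mean_lnfc=row["mean_lnfc"],
                t=row["t"],
                df=int(row["df"]),
                p=row["p"],
                fc=row["fc"],
                significant=bool(row["significant"]),
                variable=bool(row["variable"]),
                soi=bool(row["soi"]),
            )
        )
    return records
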