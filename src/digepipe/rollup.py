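"""Isoform aggregation and protein-level statistics.

A single protein usually appears on a 2D gel as a horizontal train of spots
(charge/mass isoforms).  To quantify the protein rather than any one
isoform, the total-volume-normalized abundances of its member spots are
summed per sample.  On these totals the module provides the paired
statistics used for GFAP (glial fibrillary acidic protein, the astrocyte
intermediate filament): a two-sided paired t-test on log totals across
patients, the cytosol-to-nuclear solubility ratio that tracks astrogliosis,
and the correlation of the per-patient fold change with the within-patient
spike-frequency difference (Pearson with the t-transform p, least-squares
line, and exact small-sample Kendall tau).

Totals are only defined in total-volume mode: ratiometric abundances are
ratios to spot-specific standard levels and cannot be added across spots.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import DigeError, PatientMetadata
from .normalize import TOTAL_VOLUME, ExpressionMatrix


@dataclass
class ProteinTotal:
    """Per-sample summed abundance of one protein's isoform spots."""

    gene_symbol: str
    fraction: str
    spot_ids: tuple[str, ...]
    totals: pd.Series  # index (patient, condition)

    def per_patient(self, condition: str) -> pd.Series:
        s = self.totals.xs(condition, level="condition")
        s.name = condition
        return s

    def fold_change(self, convention: str = "HL") -> pd.Series:
        """Per-patient plain ratio of totals: H/L (default) or L/H."""
        h = self.per_patient("high")
        l = self.per_patient("low")
        fc = h / l if convention == "HL" else l / h
        fc.name = f"fc_{convention.lower()}"
        return fc


@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float
    fc_hl: float   # geometric-mean high/low ratio
    fc_lh: float
    degenerate: bool = False


@dataclass
class CorrelationResult:
    """Pearson + regression + exact Kendall summary of a paired relation."""

    r: float
    p: float
    slope: float
    intercept: float
    tau: float
    tau_p: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise DigeError("correlation requires n >= 3")


def aggregate_isoforms(expr: ExpressionMatrix, spot_ids,
                       gene_symbol: str = "") -> ProteinTotal:
    """Sum member-spot abundances per sample (total-volume mode only)."""
    if expr.mode != TOTAL_VOLUME:
        raise DigeError(
            "isoform totals are only meaningful on total-volume-normalized "
            f"abundances, got mode {expr.mode!r}"
        )
    spot_ids = tuple(spot_ids)
    if not spot_ids:
        raise DigeError("empty spot set")
    missing = [s for s in spot_ids if s not in expr.data.index]
    if missing:
        raise DigeError(f"spots not in matrix: {missing}")
    totals = expr.data.loc[list(spot_ids)].sum(axis=0)
    totals.index.names = ["patient", "condition"]
    return ProteinTotal(gene_symbol=gene_symbol.upper(), fraction=expr.fraction,
                        spot_ids=spot_ids, totals=totals)


def paired_total_test(total: ProteinTotal) -> PairedTestResult:
    """Two-sided paired t-test on ln totals (high vs low) across patients.

    Equivalent to a one-sample t-test of the per-patient ln(H/L) against 0
    with df = n_patients - 1; the reported fold changes are geometric means
    of the per-patient ratios.
    """
    h = total.per_patient("high")
    l = total.per_patient("low").reindex(h.index)
    n = len(h)
    if n < 3:
        raise DigeError("paired test requires >= 3 patients")
    lnr = np.log(h.to_numpy()) - np.log(l.to_numpy())
    mean = float(lnr.mean())
    sd = float(lnr.std(ddof=1))
    if sd == 0.0:
        return PairedTestResult(t=math.nan, df=n - 1, p=math.nan,
                                fc_hl=math.exp(mean), fc_lh=math.exp(-mean),
                                degenerate=True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTestResult(t=float(t), df=n - 1, p=float(p),
                            fc_hl=math.exp(mean), fc_lh=math.exp(-mean))


def fraction_ratio(cytosol: ProteinTotal, nuclear: ProteinTotal) -> pd.DataFrame:
    """Per-patient, per-condition cytosolic-to-nuclear total ratio.

    The soluble (cytosolic) pool of an intermediate filament protein grows
    with astrogliosis, so this ratio serves as a histology-free gliosis
    proxy: roughly 0.2-0.25 for normal tissue, rising towards 1 as gliosis
    becomes pronounced.
    """
    c = cytosol.totals
    n = nuclear.totals.reindex(c.index)
    if n.isna().any():
        missing = list(n.index[n.isna()])
        raise DigeError(f"nuclear totals missing for samples: {missing}")
    if (n == 0).any():
        raise DigeError("zero nuclear total")
    ratio = (c / n).rename("cyt_nuc_ratio")
    return ratio.reset_index().pivot(index="patient", columns="condition",
                                     values="cyt_nuc_ratio")


#: qualitative gliosis bands for the cytosol/nuclear ratio
GLIOSIS_BANDS = {"normal": (0.0, 1 / 3), "moderate": (1 / 3, 0.75),
                 "pronounced": (0.75, math.inf)}


def classify_gliosis(ratio, bands=None) -> str:
    bands = bands or GLIOSIS_BANDS
    for name, (lo, hi) in bands.items():
        if lo <= ratio < hi:
            return name
    raise DigeError(f"ratio {ratio} falls outside all bands")


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via the t-transform.

    ``t = r sqrt(n-2) / sqrt(1-r^2)`` referred to a t distribution with
    n - 2 degrees of freedom.  |r| = 1 is reported as the limit p = 0 with a
    warning (the transform diverges there).
    """
    if n < 3:
        raise DigeError("need n >= 3")
    if abs(r) > 1:
        raise DigeError(f"invalid correlation r={r}")
    if abs(r) == 1.0:
        warnings.warn("|r| = 1: p reported as the limiting value 0", stacklevel=2)
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _inversion_counts(n: int) -> np.ndarray:
    """Number of permutations of n items with k pairwise inversions.

    Coefficients of prod_{i=1..n} (1 + x + ... + x^(i-1)); the exact null
    distribution of the discordant-pair count of Kendall's tau.
    """
    poly = np.array([1.0])
    for i in range(1, n + 1):
        poly = np.convolve(poly, np.ones(i))
    return poly


def kendall_exact(x, y, exact: bool = True) -> tuple[float, float]:
    """Kendall tau with the exact two-sided permutation p-value.

    ``tau = (C - D) / (n(n-1)/2)``; the exact p is the fraction of all n!
    rank permutations whose |tau| is at least the observed one, computed
    from the inversion-number distribution (identical to full enumeration).
    Ties are not supported in exact mode; pass ``exact=False`` (or n > 10,
    which falls back automatically with a warning) for the normal
    approximation that handles ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DigeError("x and y must be 1-d and of equal length")
    n = x.size
    if n < 3:
        raise DigeError("Kendall correlation requires n >= 3")
    ties = (len(np.unique(x)) < n) or (len(np.unique(y)) < n)
    if exact and ties:
        raise DigeError(
            "ties present: the exact permutation p is undefined; "
            "use exact=False for the tie-corrected normal approximation"
        )
    if exact and n > 10:
        warnings.warn(
            f"n={n} > 10: falling back to the normal approximation",
            stacklevel=2,
        )
        exact = False
    if not exact:
        res = stats.kendalltau(x, y, method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    # discordant pairs between the two rank orders
    order = np.argsort(x, kind="stable")
    ry = y[order]
    m = n * (n - 1) // 2
    disc = sum(
        int(ry[a] > ry[b]) for a in range(n) for b in range(a + 1, n)
    )
    tau = (m - 2 * disc) / m
    counts = _inversion_counts(n)
    stat = abs(m - 2 * disc)
    ks = np.arange(counts.size)
    mask = np.abs(m - 2 * ks) >= stat
    p = float(counts[mask].sum() / counts.sum())
    return float(tau), p


def correlate_fc_with_spike(
    fc_lh: pd.Series, metadata: PatientMetadata
) -> CorrelationResult:
    """Correlate per-patient fold change (low/high) with delta-spike.

    Regresses the spike-frequency difference (response) on the fold change,
    so the fitted line is in the same orientation as
    ``delta_spike = slope * FC + intercept``.  Kendall tau uses the exact
    permutation p when the data are tie-free and small.
    """
    d = metadata.delta_spike
    joined = pd.concat([fc_lh.rename("fc"), d], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise DigeError(f"need >= 3 patients with both values, got {len(joined)}")
    x = joined["fc"].to_numpy(dtype=float)
    y = joined["delta_spike"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DigeError("correlation undefined for constant inputs")
    r, p = stats.pearsonr(x, y)
    reg = stats.linregress(x, y)
    n = len(joined)
    ties = (len(np.unique(x)) < n) or (len(np.unique(y)) < n)
    tau, tau_p = kendall_exact(x, y, exact=not ties and n <= 10)
    return CorrelationResult(r=float(r), p=float(p), slope=float(reg.slope),
                             intercept=float(reg.intercept), tau=tau,
                             tau_p=tau_p, n=n)
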