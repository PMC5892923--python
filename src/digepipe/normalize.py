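"""Normalization of raw spot volumes and technical-replicate averaging.

Two schemes are supported, mirroring the two analyses the gel software and
the downstream statistics rely on:

``ratiometric``
    Each sample channel is divided spot-wise by the pooled-standard channel
    of the same gel, and the resulting ratios are centred by their per-image
    median.  Ratios to the common internal standard make spots comparable
    across gels; the median centring removes any residual per-image gain so
    the output is exactly invariant to multiplying an image by a constant.
    Ratios of *different* spots are not comparable to each other under this
    scheme (each spot carries its own standard level).

``total_volume``
    Each image's volumes are scaled to sum to 1e6 ("parts per million of the
    image's total fluorescence").  Spot values become comparable to one
    another within and across images, which is what isoform roll-up sums and
    cross-fraction clustering require.

Replicate averaging takes the arithmetic mean of the normalized abundances
over a patient's dye-swap gels, yielding one value per spot per biological
sample (patient x condition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    CONDITIONS,
    SAMPLE_DYES,
    STANDARD_DYE,
    DigeError,
    SpotVolumeTable,
    StudyDesign,
)

RATIOMETRIC = "ratiometric"
TOTAL_VOLUME = "total_volume"

#: scale of total-volume normalization: each image sums to this
TOTAL_VOLUME_SCALE = 1.0e6


@dataclass
class ExpressionMatrix:
    """Normalized, replicate-averaged spot abundances per biological sample.

    ``data`` is spots x samples with a ``(patient, condition)`` MultiIndex on
    the columns; ``mode`` records which normalization produced it, since the
    roll-up statistics are only meaningful in total-volume mode.
    """

    data: pd.DataFrame
    mode: str
    fraction: str
    replicate_averaged: bool = True

    def __post_init__(self) -> None:
        if self.mode not in (RATIOMETRIC, TOTAL_VOLUME):
            raise DigeError(f"unknown normalization mode {self.mode!r}")
        if (self.data.to_numpy() <= 0).any():
            raise DigeError("expression matrix contains non-positive values")

    @property
    def patients(self) -> list[str]:
        return list(self.data.columns.get_level_values(0).unique())

    def sample(self, patient: str, condition: str) -> pd.Series:
        return self.data[(patient, condition)]

    def hl_ratio(self) -> pd.DataFrame:
        """Per-spot high/low abundance ratio, one column per patient."""
        out = {p: self.data[(p, "high")] / self.data[(p, "low")] for p in self.patients}
        return pd.DataFrame(out)


def _channel_frame(columns: list[tuple[str, str, str]], values: list[np.ndarray],
                   index: pd.Index, mode: str, fraction: str) -> pd.DataFrame:
    cols = pd.MultiIndex.from_tuples(columns, names=["patient", "condition", "gel_id"])
    df = pd.DataFrame(np.column_stack(values), index=index, columns=cols)
    df = df.sort_index(axis=1)
    df.attrs["mode"] = mode
    df.attrs["fraction"] = fraction
    return df


def ratiometric_normalize(table: SpotVolumeTable, design: StudyDesign) -> pd.DataFrame:
    """Ratio-to-standard abundances with per-image median centring.

    Returns a spots x channels frame whose columns are labelled
    ``(patient, condition, gel_id)``; the standard channels are consumed and
    not emitted.
    """
    vol = table.volumes
    columns: list[tuple[str, str, str]] = []
    values: list[np.ndarray] = []
    for gel in design.gels_for(table.fraction):
        std = vol[(gel.gel_id, STANDARD_DYE)].to_numpy()
        if (std <= 0).any():
            raise DigeError(f"gel {gel.gel_id!r}: non-positive standard volume")
        for dye in SAMPLE_DYES:
            patient, condition = design.sample_of(gel.gel_id, dye)
            ratio = vol[(gel.gel_id, dye)].to_numpy() / std
            ratio = ratio / np.median(ratio)
            columns.append((patient, condition, gel.gel_id))
            values.append(ratio)
    return _channel_frame(columns, values, vol.index, RATIOMETRIC, table.fraction)


def total_volume_normalize(
    table: SpotVolumeTable,
    design: StudyDesign | None = None,
    include_standard: bool = False,
    scale: float = TOTAL_VOLUME_SCALE,
) -> pd.DataFrame:
    """Scale every image so its spot volumes sum to ``scale`` (default 1e6).

    With a ``design`` the sample channels are relabelled
    ``(patient, condition, gel_id)`` (standard channels dropped unless
    ``include_standard``); without one the original ``(gel, dye)`` columns
    are kept and all channels normalized in place.
    """
    vol = table.volumes
    if vol.shape[0] == 0:
        raise DigeError("empty spot set")
    if design is None:
        return vol / vol.sum(axis=0) * scale
    columns: list[tuple[str, str, str]] = []
    values: list[np.ndarray] = []
    for gel in design.gels_for(table.fraction):
        dyes = (STANDARD_DYE,) + SAMPLE_DYES if include_standard else SAMPLE_DYES
        for dye in dyes:
            v = vol[(gel.gel_id, dye)].to_numpy()
            sample = design.sample_of(gel.gel_id, dye)
            patient, condition = sample if sample else ("pool", "standard")
            columns.append((patient, condition, gel.gel_id))
            values.append(v / v.sum() * scale)
    return _channel_frame(columns, values, vol.index, TOTAL_VOLUME, table.fraction)


def average_replicates(
    channels: pd.DataFrame,
    design: StudyDesign | None = None,
    mode: str | None = None,
    fraction: str | None = None,
) -> ExpressionMatrix:
    """Arithmetic mean over dye-swap replicates -> one column per sample.

    ``channels`` must carry ``(patient, condition, gel_id)`` columns as
    produced by the normalizers.  With a ``design``, completeness is checked:
    every (patient, condition) of the fraction must have at least one
    measurement.
    """
    mode = mode or channels.attrs.get("mode")
    fraction = fraction or channels.attrs.get("fraction")
    if mode is None or fraction is None:
        raise DigeError("mode and fraction must be known to build an ExpressionMatrix")
    data = channels.T.groupby(level=["patient", "condition"]).mean().T
    if design is not None:
        expected = {(p, c) for p in design.patients(fraction) for c in CONDITIONS}
        got = set(map(tuple, data.columns))
        missing = expected - got
        if missing:
            raise DigeError(f"samples with zero measurements: {sorted(missing)}")
    return ExpressionMatrix(data=data, mode=mode, fraction=fraction)


def unite_fractions(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Stack total-volume matrices of several fractions into one.

    Rows are re-indexed by (fraction, spot_id).  Ratiometric matrices cannot
    be united: their values are ratios to a spot-specific standard level and
    are not comparable across spots, so cross-fraction joint analyses are
    restricted to total-volume mode.
    """
    if not matrices:
        raise DigeError("no matrices to unite")
    for m in matrices:
        if m.mode != TOTAL_VOLUME:
            raise DigeError(
                "cross-fraction union is only defined for total-volume "
                f"normalization (got {m.mode!r} for fraction {m.fraction!r})"
            )
    frames = []
    for m in matrices:
        f = m.data.copy()
        f.index = pd.MultiIndex.from_product(
            [[m.fraction], f.index], names=["fraction", "spot_id"]
        )
        frames.append(f)
    data = pd.concat(frames, axis=0)
    return ExpressionMatrix(data=data, mode=TOTAL_VOLUME, fraction="all",
                            replicate_averaged=all(m.replicate_averaged for m in matrices))
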