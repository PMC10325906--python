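"""Closed-form assay quantifications.

Small, pure formulas used to quantify the wet-bench readouts of the study
design: lysosomal (autophagic) flux by inhibitor subtraction, acute
degradation deltas, the HTRF demethylase-activity DF%, ChIP enrichment as
percent of input, bisulfite-clone percent-methylation summaries, and the
Pearson colocalization coefficient over a cytoplasmic pixel mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "WellReading",
    "CloneMatrix",
    "QuantSeries",
    "htrf_df_percent",
    "lysosomal_flux",
    "treatment_delta",
    "percent_input",
    "clone_methylation_summary",
    "pearson_colocalization",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WellReading:
    """One HTRF well: time-resolved fluorescence at 665 nm and 620 nm."""

    f665: float
    f620: float

    def __post_init__(self) -> None:
        if self.f665 < 0:
            raise ValueError("665 nm reading must be >= 0")
        if self.f620 <= 0:
            raise ValueError("620 nm reading must be > 0")

    @property
    def ratio(self) -> float:
        return self.f665 / self.f620


@dataclass
class CloneMatrix:
    """Bisulfite-sequencing clone calls: clones x CpG positions, True for a
    methylated call.  Missing calls are not modelled; matrices are complete."""

    calls: np.ndarray
    cpg_labels: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=bool)
        if self.calls.ndim != 2 or self.calls.shape[0] < 1 or self.calls.shape[1] < 1:
            raise ValueError("clone matrix must be 2-D with >= 1 clone and >= 1 CpG")
        if len(self.cpg_labels) != self.calls.shape[1]:
            raise ValueError("CpG labels must match matrix columns")


@dataclass(frozen=True)
class QuantSeries:
    """A normalised band / intensity value with its normalisation tag
    (``internal-control`` or ``total-protein``)."""

    value: float
    normalization: str

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("normalised quantification must be >= 0")


def htrf_df_percent(plus: WellReading, minus: WellReading) -> float:
    """Demethylase-activity DF%:
    ``((665/620 with enzyme) / (665/620 without enzyme) - 1) * 100``."""
    if minus.ratio <= 0:
        raise ValueError("enzyme(-) 665/620 ratio must be > 0")
    return (plus.ratio / minus.ratio - 1.0) * 100.0


def _check_tags(a: QuantSeries, b: QuantSeries) -> None:
    if a.normalization != b.normalization:
        raise ValueError(
            f"mixed normalisation tags: {a.normalization!r} vs {b.normalization!r}"
        )


def lysosomal_flux(level_inhibited: QuantSeries, level_vehicle: QuantSeries) -> float:
    """Lysosomal degradation flux: protein level under lysosomal inhibition
    (bafilomycin A1) minus the vehicle level.  Negative flux is reported,
    not clipped — it is meaningful assay noise — and flagged in the log."""
    _check_tags(level_inhibited, level_vehicle)
    flux = level_inhibited.value - level_vehicle.value
    if flux < 0:
        logger.warning("negative lysosomal flux (%g); reporting as-is", flux)
    return flux


def treatment_delta(level_post: QuantSeries, level_pre: QuantSeries) -> float:
    """Acute degradation delta: level after treatment minus level before."""
    _check_tags(level_post, level_pre)
    return level_post.value - level_pre.value


def percent_input(ip_signal: float, input_signal: float,
                  input_fraction: float) -> float:
    """ChIP enrichment as percent of total chromatin:
    ``100 * IP / (input / input_fraction)``.

    ``input_fraction`` is the fraction of chromatin used for the input
    control (e.g. 0.01 for a 1% input) and must be given explicitly.
    """
    if input_signal <= 0:
        raise ValueError("input signal must be > 0")
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    if ip_signal < 0:
        raise ValueError("IP signal must be >= 0")
    return 100.0 * ip_signal / (input_signal / input_fraction)


def clone_methylation_summary(matrix: CloneMatrix) -> tuple[np.ndarray, float]:
    """Percent methylated clones per CpG and overall percent methylated
    calls: ``(per_cpg_percent, overall_percent)``."""
    per_cpg = 100.0 * matrix.calls.mean(axis=0)
    overall = float(100.0 * matrix.calls.mean())
    return per_cpg, overall


def pearson_colocalization(intensities_a: Sequence[float] | np.ndarray,
                           intensities_b: Sequence[float] | np.ndarray,
                           mask: Sequence[bool] | np.ndarray | None = None
                           ) -> float:
    """Pearson correlation of two channels' pixel intensities within a mask
    (e.g. the cytoplasmic region of one cell).

    Requires at least two masked pixels and non-constant intensities in both
    channels (the correlation is undefined otherwise).
    """
    a = np.asarray(intensities_a, dtype=float).ravel()
    b = np.asarray(intensities_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        if m.shape != a.shape:
            raise ValueError("mask shape differs from channels")
        a, b = a[m], b[m]
    if a.size < 2:
        raise ValueError("need >= 2 masked pixels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant channel within mask; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])
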