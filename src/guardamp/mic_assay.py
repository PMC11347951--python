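"""Minimum inhibitory concentration (MIC) from serial-dilution growth assays.

A microplate assay holds a two-fold dilution ladder of the peptide, a
growth control (bacteria, no peptide) and medium-only blanks, each read as
an OD600 time series.  After background subtraction, a per-well growth
metric (max OD by default) is compared with the growth control: a well is
"fully inhibited" when its metric is at most ``tolerance`` times the
control metric.  The MIC is the lowest concentration such that it and every
higher concentration are fully inhibited; if even the top concentration
grows, the result is censored as ">top".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DilutionSeries",
    "Well",
    "PlateAssay",
    "MicResult",
    "plan_dilution",
    "subtract_background",
    "growth_metric",
    "call_mic",
    "mic_fold_change",
]

ROLES = ("sample", "growth-control", "blank")


@dataclass(frozen=True)
class DilutionSeries:
    """Descending geometric concentration ladder (molar units as given)."""

    top: float
    factor: float
    n_points: int
    concentrations: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.top <= 0:
            raise ValueError("top concentration must be > 0")
        if self.factor <= 1:
            raise ValueError("dilution factor must be > 1")
        if self.n_points < 1:
            raise ValueError("need at least one dilution point")
        if not self.concentrations:
            conc = tuple(self.top / self.factor**i for i in range(self.n_points))
            object.__setattr__(self, "concentrations", conc)

    @property
    def lowest(self) -> float:
        return self.concentrations[-1]


@dataclass
class Well:
    concentration: float  # 0 for growth-control and blank wells
    role: str
    od: np.ndarray

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown well role {self.role!r}")
        self.od = np.asarray(self.od, dtype=float)


@dataclass
class PlateAssay:
    """OD600 time grid for a dilution series plus controls and blanks."""

    times: np.ndarray  # hours, uniform grid
    wells: list[Well]
    background_corrected: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for w in self.wells:
            if w.od.shape != self.times.shape:
                raise ValueError("well OD series does not match the time grid")

    def by_role(self, role: str) -> list[Well]:
        return [w for w in self.wells if w.role == role]


@dataclass(frozen=True)
class MicResult:
    mic: float | None  # molar; None when censored
    censored: bool
    top_tested: float
    growth_metric_per_well: dict[float, float]
    inhibition_fraction_per_well: dict[float, float]
    monotone: bool = True

    @property
    def label(self) -> str:
        return f">{self.top_tested:g}" if self.censored else f"{self.mic:g}"


def plan_dilution(top: float, n_points: int = 16, factor: float = 2.0) -> DilutionSeries:
    """Geometric dilution ladder ``top / factor**i`` for i = 0..n_points-1."""
    return DilutionSeries(top=top, factor=factor, n_points=n_points)


def subtract_background(plate: PlateAssay) -> PlateAssay:
    """Subtract the mean blank series from every non-blank well, floored at 0."""
    blanks = plate.by_role("blank")
    if not blanks:
        raise ValueError("no blank (medium-only) well on the plate")
    blank_mean = np.mean([w.od for w in blanks], axis=0)
    corrected = []
    for w in plate.wells:
        if w.role == "blank":
            corrected.append(Well(w.concentration, w.role, w.od.copy()))
        else:
            corrected.append(
                Well(w.concentration, w.role, np.maximum(w.od - blank_mean, 0.0))
            )
    return PlateAssay(times=plate.times, wells=corrected, background_corrected=True)


def growth_metric(
    series: np.ndarray, times: np.ndarray | None = None, kind: str = "max"
) -> float:
    """Scalar growth summary of a background-corrected OD series.

    ``max`` (default) is the peak OD over the window; ``auc`` integrates
    the curve over time (trapezoid) and requires ``times``.
    """
    series = np.asarray(series, dtype=float)
    if kind == "max":
        return float(series.max()) if series.size else 0.0
    if kind == "auc":
        if times is None:
            raise ValueError("AUC metric needs the time grid")
        return float(np.trapezoid(series, np.asarray(times, dtype=float)))
    raise ValueError(f"unknown growth metric {kind!r}")


def call_mic(
    plate: PlateAssay,
    series: DilutionSeries,
    inhibition_tolerance: float = 0.1,
    metric: str = "max",
) -> MicResult:
    """Call the MIC as the lowest concentration with full inhibition.

    Full inhibition means the well's growth metric is <= ``tolerance`` times
    the growth-control metric.  Inhibited wells must form a contiguous top
    segment of the ladder; wells growing above an inhibited concentration
    are reported as a monotonicity warning, and the MIC is the lowest
    concentration of the contiguous fully-inhibited top segment.
    """
    if not plate.background_corrected:
        plate = subtract_background(plate)
    controls = plate.by_role("growth-control")
    if not controls:
        raise ValueError("no growth-control well on the plate")
    control_metric = float(
        np.mean([growth_metric(w.od, plate.times, metric) for w in controls])
    )
    if control_metric <= 0:
        raise ValueError("growth control shows no growth; assay invalid")

    metrics: dict[float, float] = {}
    inhibition: dict[float, float] = {}
    for conc in series.concentrations:
        wells = [w for w in plate.by_role("sample") if math.isclose(w.concentration, conc)]
        if not wells:
            raise ValueError(f"no sample well at concentration {conc:g}")
        m = float(np.mean([growth_metric(w.od, plate.times, metric) for w in wells]))
        metrics[conc] = m
        inhibition[conc] = 1.0 - m / control_metric

    inhibited = [metrics[c] <= inhibition_tolerance * control_metric
                 for c in series.concentrations]
    # contiguous fully-inhibited top segment (concentrations are descending)
    top_run = 0
    for flag in inhibited:
        if not flag:
            break
        top_run += 1
    monotone = not any(inhibited[top_run:])
    if not monotone:
        warnings.warn(
            "non-monotone inhibition pattern: growth above an inhibited well",
            stacklevel=2,
        )
    if top_run == 0:
        return MicResult(None, True, series.top, metrics, inhibition, monotone)
    mic = series.concentrations[top_run - 1]
    return MicResult(mic, False, series.top, metrics, inhibition, monotone)


def mic_fold_change(
    mic_treated: MicResult | float, mic_untreated: MicResult | float
) -> tuple[float, float]:
    """Ratio of treated to untreated MIC, raw and at one significant figure.

    Censored inputs cannot form a finite ratio and raise ``ValueError``.
    """
    def value(m):
        if isinstance(m, MicResult):
            if m.censored:
                raise ValueError("censored MIC: fold change undefined")
            return m.mic
        return float(m)

    t, u = value(mic_treated), value(mic_untreated)
    if u <= 0:
        raise ValueError("untreated MIC must be positive")
    ratio = t / u
    exponent = math.floor(math.log10(abs(ratio)))
    one_sf = round(ratio / 10**exponent) * 10**exponent
    return ratio, one_sf
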