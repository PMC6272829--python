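"""SRM-based quantification and method validation.

Calibration by unweighted ordinary least squares (peak area y against
standard concentration x in ug/mL), LOD/LOQ from signal-to-noise thresholds
(3 and 10), trapezoidal peak integration with a median baseline, content
calculation back to mg per g of dried root, and the standard validation
statistics (recovery, relative standard deviation, dilution series).

Sample-preparation constants default to 0.2 g of powdered root extracted in
25 mL of methanol, the preparation the shipped configuration describes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "SRMTransition",
    "Chromatogram",
    "CalibrationCurve",
    "PeakIntegration",
    "LodLoq",
    "QuantResult",
    "QuantConfig",
    "load_default_quant_config",
    "fit_calibration",
    "integrate_srm_peak",
    "estimate_lod_loq",
    "quantify",
    "recovery",
    "rsd",
    "dilution_series",
]


@dataclass(frozen=True)
class SRMTransition:
    """One selected-reaction-monitoring precursor -> product pair."""

    analyte: str
    precursor_mz: float
    product_mz: float
    collision_energy: float = 35.0  # normalized collision energy, %
    isolation_width: float = 1.0    # +- Da

    def __post_init__(self):
        if self.product_mz >= self.precursor_mz:
            raise ValueError("product m/z must be below precursor m/z")


@dataclass
class Chromatogram:
    """A single-trace chromatogram on a strictly increasing time axis."""

    times: np.ndarray   # minutes
    intensities: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if self.times.size < 5:
            raise ValueError("need at least 5 chromatogram points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0")


@dataclass(frozen=True)
class CalibrationCurve:
    analyte: str
    slope: float
    intercept: float
    r2: float
    range_low: float    # ug/mL
    range_high: float

    def __post_init__(self):
        if not self.range_low < self.range_high:
            raise ValueError("range_low must be below range_high")
        if not 0 <= self.r2 <= 1:
            raise ValueError("r2 must lie in [0, 1]")

    def predict_area(self, conc: float) -> float:
        return self.slope * conc + self.intercept

    def invert(self, area: float) -> float:
        if self.slope == 0:
            raise ValueError("cannot invert a zero-slope curve")
        return (area - self.intercept) / self.slope


@dataclass(frozen=True)
class PeakIntegration:
    area: float
    height: float
    snr: float
    baseline: float
    zero_noise: bool = False


@dataclass(frozen=True)
class LodLoq:
    lod: float
    loq: float
    lod_interpolated: bool = False
    loq_interpolated: bool = False
    lod_open_ended: bool = False
    loq_open_ended: bool = False


@dataclass(frozen=True)
class QuantResult:
    sample_id: str
    analyte: str
    solution_conc: float   # ug/mL in the extract
    content: float         # mg per g dry weight
    below_loq: bool = False
    above_range: bool = False
    clipped: bool = False


def fit_calibration(
    points: Sequence[tuple[float, float]], analyte: str = ""
) -> CalibrationCurve:
    """Unweighted OLS of peak area on concentration.

    r-squared is the squared Pearson correlation; the working range is
    [min conc, max conc]. Requires at least 3 distinct concentration levels.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 calibration points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct concentration levels")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in concentrations")
    res = stats.linregress(x, y)
    return CalibrationCurve(
        analyte=analyte,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(min(res.rvalue**2, 1.0)),
        range_low=float(x.min()),
        range_high=float(x.max()),
    )


def integrate_srm_peak(
    chrom: Chromatogram, window: tuple[float, float]
) -> PeakIntegration:
    """Integrate one SRM peak inside a retention-time window.

    Baseline is the median of out-of-window points; area is the trapezoidal
    integral of the baseline-subtracted trace inside the window; S/N is the
    baseline-subtracted apex height over the standard deviation of
    out-of-window residuals. The apex is located on a moving-average-smoothed
    copy of the window and the height read from the raw trace there, so a
    single baseline noise spike cannot masquerade as the peak apex (a plain
    max is biased upward at low S/N). A perfectly flat out-of-window region
    gives infinite S/N with the zero-noise flag set.
    """
    t0, t1 = window
    if t0 >= t1:
        raise ValueError("window start must precede window end")
    if t0 < chrom.times[0] or t1 > chrom.times[-1]:
        raise ValueError("window must lie within the chromatogram time range")
    inside = (chrom.times >= t0) & (chrom.times <= t1)
    outside = ~inside
    if not inside.any():
        raise ValueError("window contains no chromatogram points")
    if not outside.any():
        raise ValueError("window must leave baseline points outside")
    baseline = float(np.median(chrom.intensities[outside]))
    corrected = chrom.intensities - baseline
    area = float(np.trapezoid(corrected[inside], chrom.times[inside]))
    segment = corrected[inside]
    width = max(3, (segment.size // 10) | 1)
    if segment.size >= width:
        kernel = np.ones(width) / width
        smoothed = np.convolve(segment, kernel, mode="same")
        apex = int(np.argmax(smoothed))
    else:
        apex = int(np.argmax(segment))
    height = float(segment[apex])
    noise = float(np.std(chrom.intensities[outside] - baseline, ddof=1))
    if noise == 0:
        return PeakIntegration(area, height, float("inf"), baseline, True)
    return PeakIntegration(area, height, height / noise, baseline)


def _interp_crossing(
    concs: np.ndarray, snrs: np.ndarray, threshold: float
) -> tuple[float, bool, bool]:
    """First concentration where S/N reaches threshold (linear interpolation).

    Returns (value, interpolated?, open_ended?).
    """
    reached = snrs >= threshold
    if not reached.any():
        return float("nan"), False, True
    i = int(np.argmax(reached))
    if snrs[i] == threshold or i == 0:
        return float(concs[i]), False, False
    c0, c1 = concs[i - 1], concs[i]
    s0, s1 = snrs[i - 1], snrs[i]
    conc = c0 + (threshold - s0) / (s1 - s0) * (c1 - c0)
    return float(conc), True, False


def estimate_lod_loq(
    dilution_responses: Sequence[tuple[float, float]],
) -> LodLoq:
    """LOD and LOQ from a (concentration, S/N) dilution series.

    LOD is where S/N reaches 3, LOQ where it reaches 10, with linear
    interpolation between bracketing levels. S/N must be nondecreasing in
    concentration; a series that never reaches a threshold yields NaN with
    the open-ended flag.
    """
    if len(dilution_responses) < 2:
        raise ValueError("need at least 2 dilution levels")
    pairs = sorted((float(c), float(s)) for c, s in dilution_responses)
    concs = np.array([p[0] for p in pairs])
    snrs = np.array([p[1] for p in pairs])
    if np.any(np.diff(snrs) < 0):
        raise ValueError("S/N must be nondecreasing in concentration")
    lod, lod_i, lod_open = _interp_crossing(concs, snrs, 3.0)
    loq, loq_i, loq_open = _interp_crossing(concs, snrs, 10.0)
    return LodLoq(lod, loq, lod_i, loq_i, lod_open, loq_open)


def quantify(
    area: float,
    curve: CalibrationCurve,
    extract_volume: float = 25.0,   # mL
    sample_mass: float = 0.2,       # g
    dilution_factor: float = 1.0,
    sample_id: str = "",
    loq: float | None = None,
) -> QuantResult:
    """Back-calculate content in mg per g dry weight from a peak area.

    solution_conc = (area - intercept) / slope * dilution_factor;
    content = solution_conc * extract_volume / sample_mass / 1000.
    Injected concentrations outside the calibrated range are flagged; a
    negative back-calculation is clipped to zero with a flag.
    """
    if sample_mass <= 0:
        raise ValueError("sample mass must be positive")
    if extract_volume <= 0:
        raise ValueError("extract volume must be positive")
    if dilution_factor <= 0:
        raise ValueError("dilution factor must be positive")
    injected = curve.invert(area)
    clipped = injected < 0
    injected = max(injected, 0.0)
    solution = injected * dilution_factor
    content = solution * extract_volume / sample_mass / 1000.0
    below = loq is not None and injected < loq
    above = injected > curve.range_high
    return QuantResult(
        sample_id=sample_id,
        analyte=curve.analyte,
        solution_conc=solution,
        content=content,
        below_loq=below,
        above_range=above,
        clipped=clipped,
    )


def recovery(original: float, detected: float, spiked: float) -> float:
    """Spike recovery: (detected - original) / spiked * 100."""
    if spiked <= 0:
        raise ValueError("spiked amount must be positive")
    return (detected - original) / spiked * 100.0


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation, (sample SD / mean) * 100."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("mean is zero; RSD undefined")
    return float(arr.std(ddof=1) / mean * 100.0)


def dilution_series(
    stock: float, factors: Sequence[float] | None = None
) -> list[float]:
    """Concentrations of a serial dilution, highest first.

    Default factors are the two-fold scheme 1/2, 1/4, ..., 1/128.
    """
    if stock <= 0:
        raise ValueError("stock concentration must be positive")
    if factors is None:
        factors = [2.0**-k for k in range(1, 8)]
    if any(f <= 0 for f in factors):
        raise ValueError("dilution factors must be positive")
    return sorted((stock * f for f in factors), reverse=True)


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class QuantConfig:
    transitions: dict[str, SRMTransition]
    stock_concentrations: dict[str, float]    # ug/mL
    calibration_reference: dict[str, dict]    # published line parameters
    extract_volume: float = 25.0
    sample_mass: float = 0.2
    dilution_factors: tuple[float, ...] = tuple(2.0**-k for k in range(1, 8))

    def levels(self, analyte: str) -> list[float]:
        return dilution_series(
            self.stock_concentrations[analyte], list(self.dilution_factors)
        )


def load_quant_config(path: str | Path) -> QuantConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    transitions = {
        name: SRMTransition(
            analyte=name,
            precursor_mz=float(t["precursor_mz"]),
            product_mz=float(t["product_mz"]),
            collision_energy=float(t.get("collision_energy", 35.0)),
            isolation_width=float(t.get("isolation_width", 1.0)),
        )
        for name, t in doc["transitions"].items()
    }
    return QuantConfig(
        transitions=transitions,
        stock_concentrations={
            k: float(v) for k, v in doc["stock_concentrations"].items()
        },
        calibration_reference=doc.get("calibration_reference", {}),
        extract_volume=float(doc.get("extract_volume_ml", 25.0)),
        sample_mass=float(doc.get("sample_mass_g", 0.2)),
        dilution_factors=tuple(
            float(f) for f in doc.get(
                "dilution_factors", [2.0**-k for k in range(1, 8)]
            )
        ),
    )


def load_default_quant_config() -> QuantConfig:
    path = Path(resources.files("pmqc.data").joinpath("quant_config.yaml"))  # type: ignore[arg-type]
    return load_quant_config(path)


def load_recovery_table():
    """The shipped spike/recovery validation table (three spike levels per
    analyte; found amounts are mean +- SD over replicate spikes)."""
    import pandas as pd

    path = Path(resources.files("pmqc.data").joinpath("table6_recovery.tsv"))  # type: ignore[arg-type]
    return pd.read_csv(path, sep="\t")
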