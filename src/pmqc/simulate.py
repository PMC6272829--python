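"""Seeded generators for every input class the pipeline consumes.

Emulates what the instrument would deliver: accurate-mass peak lists with
ppm-scale Gaussian mass error (multiplicative, the Orbitrap error model),
SRM chromatograms as a Gaussian peak on a white-noise baseline over the
10-minute run, calibration dilution series, and log-normal group intensity
matrices with multiplicative processing effects.

Every generator is a pure function of (inputs, seed); each draws from its
own named pseudo-random stream so adding one generator never shifts
another's numbers.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import Adduct, ElementalFormula, IonSpecies, ion_mz
from .groupstats import MONITORED_COMPOUNDS, PROCESSING_AFFECTED
from .quant import CalibrationCurve, Chromatogram
from .rules import CompoundEntry
from .spectra import FeatureRecord, FragmentPeak, MSnSpectrum

__all__ = [
    "SimConfig",
    "simulate_peaklist",
    "simulate_chromatogram",
    "simulate_calibration_points",
    "simulate_group_intensities",
    "default_group_effects",
]


@dataclass(frozen=True)
class SimConfig:
    """Shared simulation settings; a fixed seed gives bit-identical output."""

    seed: int = 0
    mass_sigma_ppm: float = 3.0       # Gaussian m/z error, ppm (Orbitrap-scale)
    rt_sigma_min: float = 0.03        # retention-time jitter, minutes
    intensity_cv: float = 0.2         # log-normal coefficient of variation
    run_time_min: float = 10.0        # chromatographic run length
    points_per_min: int = 120         # chromatogram sampling density

    def __post_init__(self):
        if self.mass_sigma_ppm < 0 or self.rt_sigma_min < 0:
            raise ValueError("sigmas must be >= 0")
        if self.intensity_cv < 0:
            raise ValueError("intensity CV must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        """A generator for one named stream, derived from (seed, stream)."""
        return np.random.default_rng([self.seed, zlib.crc32(stream.encode())])


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv**2)))


def _perturb_mz(mz: float, rng: np.random.Generator, sigma_ppm: float) -> float:
    return mz * (1.0 + rng.normal(0.0, sigma_ppm) * 1e-6)


def _perturb_tree(
    tree: MSnSpectrum, rng: np.random.Generator, cfg: SimConfig
) -> MSnSpectrum:
    sigma = _lognormal_sigma(cfg.intensity_cv)
    peaks = []
    for p in tree.peaks:
        # high-resolution fragment values get independent ppm error; nominal
        # (unit-resolution ion-trap) values stay on the integer grid
        mz = p.mz if p.is_nominal else _perturb_mz(p.mz, rng, cfg.mass_sigma_ppm)
        inten = p.relative_intensity * rng.lognormal(0.0, sigma)
        peaks.append((mz, inten))
    base = max(i for _, i in peaks)
    new_peaks = [FragmentPeak(mz, i / base * 100.0) for mz, i in peaks]
    children = [_perturb_tree(c, rng, cfg) for c in tree.children]
    # keep the child-precursor link consistent with the (unperturbed) parent
    return MSnSpectrum(
        level=tree.level,
        precursor_mz=tree.precursor_mz,
        peaks=new_peaks,
        children=children,
    )


def simulate_peaklist(
    library: Sequence[CompoundEntry],
    cfg: SimConfig,
    n_decoys: int = 0,
) -> list[FeatureRecord]:
    """Synthetic feature records for every library compound.

    Precursor m/z values are the theoretical adduct masses (computed from the
    entry's neutral formula when present, else its recorded ion m/z) under
    Gaussian ppm error; fragment trees are copied with independent m/z and
    intensity perturbation; retention times jitter by ``rt_sigma_min``.
    Optional decoy features carry random precursors and fragments placed away
    from any library value.
    """
    if not library:
        raise ValueError("library must be non-empty")
    rng = cfg.rng("peaklist")
    records = []
    for entry in library:
        ions = []
        for mz, adduct in entry.ions:
            if entry.neutral_formula is not None and adduct is not None:
                mz = ion_mz(IonSpecies(entry.neutral_formula, adduct))
            ions.append((_perturb_mz(mz, rng, cfg.mass_sigma_ppm), adduct))
        tree = None
        if entry.spectra is not None:
            tree = _perturb_tree(entry.spectra, rng, cfg)
        rt = max(0.0, entry.rt + rng.normal(0.0, cfg.rt_sigma_min))
        records.append(
            FeatureRecord(
                id=f"sim_{entry.id}",
                rt=rt,
                precursor_ions=ions,
                spectra=tree,
                origin_flags=frozenset({"SIM"}),
            )
        )
    for k in range(n_decoys):
        mz = float(rng.uniform(150.0, 1000.0))
        n_peaks = int(rng.integers(2, 6))
        frag_mz = np.sort(rng.uniform(80.0, mz - 20.0, size=n_peaks))[::-1]
        inten = rng.uniform(5.0, 100.0, size=n_peaks)
        inten[0] = 100.0
        peaks = [FragmentPeak(float(m), float(i)) for m, i in zip(frag_mz, inten)]
        records.append(
            FeatureRecord(
                id=f"decoy_{k + 1}",
                rt=float(rng.uniform(0.5, cfg.run_time_min)),
                precursor_ions=[(mz, None)],
                spectra=MSnSpectrum(2, mz, peaks),
                origin_flags=frozenset({"DECOY"}),
            )
        )
    return records


def simulate_chromatogram(
    height: float,
    rt: float,
    sigma_t: float,
    noise_sd: float,
    cfg: SimConfig,
    stream: str = "chromatogram",
) -> Chromatogram:
    """Gaussian peak plus white noise on a uniform grid over the run time."""
    if sigma_t <= 0:
        raise ValueError("peak width sigma_t must be positive")
    if noise_sd < 0:
        raise ValueError("noise SD must be >= 0")
    rng = cfg.rng(stream)
    n = int(cfg.run_time_min * cfg.points_per_min) + 1
    t = np.linspace(0.0, cfg.run_time_min, n)
    signal = height * np.exp(-0.5 * ((t - rt) / sigma_t) ** 2)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=n)
    baseline_offset = 10.0 * noise_sd  # keep intensities non-negative
    return Chromatogram(times=t, intensities=np.clip(signal + baseline_offset, 0.0, None))


def simulate_calibration_points(
    curve: CalibrationCurve,
    levels: Sequence[float],
    cfg: SimConfig,
    noise_fraction: float = 0.0,
    stream: str = "calibration",
) -> list[tuple[float, float]]:
    """Areas on a published calibration line, optionally with proportional
    Gaussian noise (sigma = noise_fraction x signal)."""
    rng = cfg.rng(stream)
    points = []
    for conc in levels:
        area = curve.predict_area(conc)
        if noise_fraction > 0:
            area += rng.normal(0.0, noise_fraction * abs(area))
        points.append((float(conc), float(area)))
    return points


def default_group_effects(fold: float = 3.0) -> dict[str, float]:
    """Fold changes in the processed group: ``fold`` for the eight
    processing-affected markers, 1.0 elsewhere."""
    return {
        c: (fold if c in PROCESSING_AFFECTED else 1.0)
        for c in MONITORED_COMPOUNDS
    }


def simulate_group_intensities(
    effects: Mapping[str, float] | None = None,
    cfg: SimConfig = SimConfig(),
    n_batches: int = 10,
    n_replicates: int = 3,
    groups: tuple[str, str] = ("CPM", "PPM"),
    base_means: Mapping[str, float] | None = None,
    zero_inflation: float = 0.0,
) -> pd.DataFrame:
    """Long-format EIC intensities for a two-group batch design.

    Intensities are log-normal around a per-compound base mean (log-spaced
    over 1e4..1e6 by default) with coefficient of variation
    ``cfg.intensity_cv``; the second group's mean is multiplied by the
    per-compound fold in ``effects``. ``zero_inflation`` zeroes a random
    fraction of observations to exercise the missing -> zero rule.
    """
    if effects is None:
        effects = default_group_effects()
    compounds = list(effects)
    if base_means is None:
        levels = np.logspace(4, 6, num=len(compounds))
        base_means = dict(zip(compounds, levels))
    if not 0 <= zero_inflation < 1:
        raise ValueError("zero_inflation must lie in [0, 1)")
    rng = cfg.rng("group_intensities")
    sigma = _lognormal_sigma(cfg.intensity_cv)
    rows = []
    for group_index, group in enumerate(groups):
        for batch in range(1, n_batches + 1):
            for rep in range(1, n_replicates + 1):
                for compound in compounds:
                    mean = base_means[compound]
                    if group_index == 1:
                        mean = mean * effects[compound]
                    # log-normal with the requested arithmetic mean and CV
                    mu = np.log(mean) - 0.5 * sigma**2
                    value = float(rng.lognormal(mu, sigma))
                    if zero_inflation and rng.random() < zero_inflation:
                        value = 0.0
                    rows.append((group, batch, rep, compound, value))
    return pd.DataFrame(
        rows, columns=["group", "batch", "replicate", "compound", "area"]
    )
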