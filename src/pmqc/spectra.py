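"""MS^n spectral trees: data model, MGF/JSON/mzML input, adduct pairing and
neutral-loss annotation.

The canonical fixture format is a JSON tree dialect (one object per feature
with nested ms2/ms3 blocks) because MGF cannot carry MS^n nesting; MGF covers
plain MS2 peak lists and mzML reading maps MS2 scans only.

Fragment m/z tolerances are two-tier: high-resolution values (>= 3 printed
decimals) are matched at +-0.01 Da, nominal integer values at +-0.5 Da, since
real annotation tables mix 4-decimal MS2 values with integer ion-trap MS3
values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .chem import Adduct, PROTON_MASS

__all__ = [
    "FRAGMENT_TOL_EXACT",
    "FRAGMENT_TOL_NOMINAL",
    "NEUTRAL_LOSS_LIBRARY",
    "FragmentPeak",
    "MSnSpectrum",
    "FeatureRecord",
    "NeutralLossHit",
    "AdductAssignment",
    "PeaklistFormat",
    "is_nominal",
    "fragment_tolerance",
    "mz_match",
    "read_peaklist",
    "write_json_tree",
    "detect_adducts",
    "neutral_losses",
    "nearest_losses",
]

FRAGMENT_TOL_EXACT = 0.01    # Da, for high-resolution (>=3 decimals) values
FRAGMENT_TOL_NOMINAL = 0.5   # Da, for integer-printed ion-trap values

#: Neutral-loss library: moiety name -> monoisotopic loss mass (Da).
NEUTRAL_LOSS_LIBRARY: dict[str, float] = {
    "hexosyl": 162.0528,        # loss of C6H10O5 (glycosidic cleavage)
    "galloyl": 152.0110,        # loss of C7H4O4
    "caffeoyl": 162.0317,       # loss of C9H6O3
    "coumaroyl": 146.0368,      # loss of C9H6O2
    "CO2": 43.9898,
    "malonyl": 86.0004,         # loss of C3H2O3
    "methyl_radical": 15.0235,  # homolytic CH3 loss (odd-electron product)
}


def is_nominal(mz: float, decimals_eps: float = 1e-6) -> bool:
    """True for integer-printed (unit-resolution) m/z values."""
    return abs(mz - round(mz)) < decimals_eps


def fragment_tolerance(
    *values: float,
    tol_exact: float = FRAGMENT_TOL_EXACT,
    tol_nominal: float = FRAGMENT_TOL_NOMINAL,
) -> float:
    """Tolerance tier for comparing m/z values: nominal if any side is."""
    return tol_nominal if any(is_nominal(v) for v in values) else tol_exact


def mz_match(a: float, b: float, **tol_kwargs) -> bool:
    return abs(a - b) <= fragment_tolerance(a, b, **tol_kwargs)


@dataclass(frozen=True)
class FragmentPeak:
    mz: float
    relative_intensity: float  # percent of base peak, (0, 100]

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if not 0 < self.relative_intensity <= 100:
            raise ValueError("relative intensity must be in (0, 100]")

    @property
    def is_nominal(self) -> bool:
        return is_nominal(self.mz)


@dataclass
class MSnSpectrum:
    """One fragmentation stage with its child stages.

    A child's precursor must match one of this spectrum's peaks within the
    fragment tolerance, and its level must be exactly one deeper.
    """

    level: int
    precursor_mz: float
    peaks: list[FragmentPeak]
    children: list["MSnSpectrum"] = field(default_factory=list)

    def __post_init__(self):
        if self.level < 2:
            raise ValueError("MS^n level must be >= 2")
        self.validate()

    def validate(self) -> None:
        for child in self.children:
            if child.level != self.level + 1:
                raise ValueError(
                    f"child level {child.level} does not follow parent {self.level}"
                )
            if not any(mz_match(child.precursor_mz, p.mz) for p in self.peaks):
                raise ValueError(
                    f"MS{child.level} precursor {child.precursor_mz} absent from "
                    f"MS{self.level} peak list"
                )
            child.validate()

    @property
    def base_peak(self) -> FragmentPeak:
        return max(self.peaks, key=lambda p: p.relative_intensity)

    def walk(self) -> Iterable["MSnSpectrum"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def all_peaks(self) -> Iterable[tuple["MSnSpectrum", FragmentPeak]]:
        for node in self.walk():
            for peak in node.peaks:
                yield node, peak


@dataclass
class FeatureRecord:
    """A chromatographic feature: precursor ion(s) plus its MS^n tree.

    ``precursor_ions`` pairs each observed m/z with an adduct hypothesis
    (or None when unassigned). ``origin_flags`` records which sample groups
    the feature was detected in (e.g. {"CPM", "PPM"}).
    """

    id: str
    rt: float
    precursor_ions: list[tuple[float, Adduct | None]]
    spectra: MSnSpectrum | None = None
    origin_flags: frozenset[str] = frozenset()
    # Optional library metadata carried by annotated fixtures.
    name: str | None = None
    family: str | None = None
    is_reference_standard: bool = False
    neutral_formula: str | None = None
    ion_formula: str | None = None

    def __post_init__(self):
        if self.rt < 0:
            raise ValueError("retention time must be >= 0")
        if not self.precursor_ions:
            raise ValueError("a feature needs at least one precursor ion")
        self.origin_flags = frozenset(self.origin_flags)

    @property
    def primary_ion(self) -> tuple[float, Adduct | None]:
        """The [M-H]- ion when labelled, else the first listed ion."""
        for mz, adduct in self.precursor_ions:
            if adduct is Adduct.M_MINUS_H:
                return mz, adduct
        return self.precursor_ions[0]


@dataclass(frozen=True)
class NeutralLossHit:
    loss_name: str
    library_mass: float
    observed_delta: float
    precursor_mz: float
    fragment_mz: float
    ambiguous: bool = False

    @property
    def delta(self) -> float:
        return self.observed_delta - self.library_mass


@dataclass(frozen=True)
class AdductAssignment:
    mz: float
    adduct: Adduct
    partner_mz: float | None
    delta: float | None


class PeaklistFormat(str, Enum):
    MGF = "mgf"
    JSON_TREE = "json"
    MZML = "mzml"


# ---------------------------------------------------------------------------
# Parsing


def _normalize_peaks(raw: Sequence[Sequence[float]]) -> list[FragmentPeak]:
    """Build peaks with relative intensities renormalized to base = 100.

    Absent/zero intensities default to 1 before normalization, so bare peak
    lists come out with every peak at 100.
    """
    pairs = []
    for entry in raw:
        entry = list(entry)
        mz = float(entry[0])
        inten = float(entry[1]) if len(entry) > 1 and entry[1] else 1.0
        pairs.append((mz, inten))
    if not pairs:
        return []
    base = max(i for _, i in pairs)
    return [FragmentPeak(mz, i / base * 100.0) for mz, i in pairs]


_ADDUCT_ALIASES = {
    "M-H": Adduct.M_MINUS_H,
    "[M-H]-": Adduct.M_MINUS_H,
    "M+HCOO": Adduct.M_PLUS_FORMATE,
    "[M+HCOO]-": Adduct.M_PLUS_FORMATE,
    "M+Cl": Adduct.M_PLUS_CL,
    "[M+Cl]-": Adduct.M_PLUS_CL,
    "2M-H": Adduct.DIMER_MINUS_H,
    "[2M-H]-": Adduct.DIMER_MINUS_H,
}


def _parse_adduct(label: str | None) -> Adduct | None:
    if label is None:
        return None
    try:
        return _ADDUCT_ALIASES[label]
    except KeyError:
        raise ValueError(f"unknown adduct label {label!r}") from None


def _tree_from_obj(obj: dict, record_id: str) -> MSnSpectrum | None:
    ms2 = obj.get("ms2")
    if ms2 is None:
        return None

    def build(node: dict, level: int, precursor: float) -> MSnSpectrum:
        peaks = _normalize_peaks(node.get("peaks", []))
        children = []
        child = node.get(f"ms{level + 1}")
        if child is not None:
            selected = child.get("selected_mz")
            if selected is None:
                selected = max(peaks, key=lambda p: p.relative_intensity).mz
            children.append(build(child, level + 1, float(selected)))
        return MSnSpectrum(level=level, precursor_mz=precursor,
                           peaks=peaks, children=children)

    precursor = ms2.get("precursor_mz")
    if precursor is None:
        precursor = obj["ions"][0]["mz"]
    try:
        return build(ms2, 2, float(precursor))
    except ValueError as exc:
        raise ValueError(f"record {record_id!r}: {exc}") from exc


def _record_from_obj(obj: dict) -> FeatureRecord:
    rid = str(obj["id"])
    ions = [
        (float(ion["mz"]), _parse_adduct(ion.get("adduct")))
        for ion in obj["ions"]
    ]
    return FeatureRecord(
        id=rid,
        rt=float(obj["rt"]),
        precursor_ions=ions,
        spectra=_tree_from_obj(obj, rid),
        origin_flags=frozenset(obj.get("flags", [])),
        name=obj.get("name"),
        family=obj.get("family"),
        is_reference_standard=bool(obj.get("standard", False)),
        neutral_formula=obj.get("neutral_formula"),
        ion_formula=obj.get("ion_formula"),
    )


def _read_json_tree(path: Path) -> list[FeatureRecord]:
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, dict):
        data = data.get("features", [])
    return [_record_from_obj(obj) for obj in data]


def _read_mgf(path: Path) -> list[FeatureRecord]:
    from pyteomics import mgf

    records = []
    with mgf.read(str(path), use_index=False) as reader:
        for i, spectrum in enumerate(reader):
            params = spectrum["params"]
            pepmass = params["pepmass"]
            precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list))
                              else pepmass)
            rt = params.get("rtinseconds")
            rt_min = float(rt) / 60.0 if rt is not None else 0.0
            title = str(params.get("title", f"feature_{i + 1}"))
            raw = list(zip(spectrum["m/z array"], spectrum["intensity array"]))
            peaks = _normalize_peaks(raw)
            tree = MSnSpectrum(level=2, precursor_mz=precursor, peaks=peaks)
            records.append(
                FeatureRecord(id=title, rt=rt_min,
                              precursor_ions=[(precursor, None)], spectra=tree)
            )
    return records


def _read_mzml(path: Path) -> list[FeatureRecord]:
    # Optional path: maps MS2 scans only; MS^n nesting is not reconstructed.
    from pyteomics import mzml

    records = []
    with mzml.read(str(path)) as reader:
        for i, scan in enumerate(reader):
            if scan.get("ms level") != 2:
                continue
            precursor = float(
                scan["precursorList"]["precursor"][0]["selectedIonList"]
                ["selectedIon"][0]["selected ion m/z"]
            )
            raw = list(zip(scan["m/z array"], scan["intensity array"]))
            peaks = _normalize_peaks(raw)
            rt = 0.0
            scan_list = scan.get("scanList", {}).get("scan", [])
            if scan_list and "scan start time" in scan_list[0]:
                rt = float(scan_list[0]["scan start time"])
            records.append(
                FeatureRecord(
                    id=str(scan.get("id", f"scan_{i}")),
                    rt=rt,
                    precursor_ions=[(precursor, None)],
                    spectra=MSnSpectrum(2, precursor, peaks),
                )
            )
    return records


def read_peaklist(
    path: str | Path, format: PeaklistFormat | str | None = None
) -> list[FeatureRecord]:
    """Read feature records from MGF, JSON tree, or mzML.

    The format is inferred from the suffix when not given. An empty file
    yields an empty list with a warning; malformed records raise ``ValueError``
    naming the record.
    """
    path = Path(path)
    if format is None:
        format = {".mgf": "mgf", ".json": "json", ".mzml": "mzml"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise ValueError(f"cannot infer peak-list format from {path.name!r}")
    format = PeaklistFormat(format)
    readers = {
        PeaklistFormat.MGF: _read_mgf,
        PeaklistFormat.JSON_TREE: _read_json_tree,
        PeaklistFormat.MZML: _read_mzml,
    }
    records = readers[format](path)
    if not records:
        warnings.warn(f"no feature records found in {path}", stacklevel=2)
    return records


def _tree_to_obj(tree: MSnSpectrum) -> dict:
    obj: dict = {
        "precursor_mz": tree.precursor_mz,
        "peaks": [[p.mz, p.relative_intensity] for p in tree.peaks],
    }
    if tree.children:
        child = tree.children[0]
        sub = _tree_to_obj(child)
        sub = {"selected_mz": child.precursor_mz, **sub}
        sub.pop("precursor_mz", None)
        obj[f"ms{child.level}"] = sub
    return obj


def write_json_tree(records: Sequence[FeatureRecord], path: str | Path) -> None:
    """Serialize records to the JSON tree dialect (inverse of reading it)."""
    out = []
    for rec in records:
        obj: dict = {
            "id": rec.id,
            "rt": rec.rt,
            "ions": [
                {"mz": mz, **({"adduct": ad.value} if ad else {})}
                for mz, ad in rec.precursor_ions
            ],
        }
        if rec.name is not None:
            obj["name"] = rec.name
        if rec.family is not None:
            obj["family"] = rec.family
        if rec.is_reference_standard:
            obj["standard"] = True
        if rec.neutral_formula is not None:
            obj["neutral_formula"] = rec.neutral_formula
        if rec.ion_formula is not None:
            obj["ion_formula"] = rec.ion_formula
        if rec.spectra is not None:
            obj["ms2"] = _tree_to_obj(rec.spectra)
        obj["flags"] = sorted(rec.origin_flags)
        out.append(obj)
    with open(path, "w") as fh:
        json.dump({"features": out}, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Adduct co-occurrence and neutral losses

_PAIR_DELTAS = {
    # second-ion minus first-ion mass difference for co-eluting adduct pairs
    Adduct.M_PLUS_FORMATE: 46.0055,  # HCOOH attachment relative to [M-H]-
    Adduct.M_PLUS_CL: 35.9767,       # HCl attachment relative to [M-H]-
}


def detect_adducts(
    coeluting_mzs: Sequence[float], tol: float = 0.01
) -> list[AdductAssignment]:
    """Assign adduct hypotheses to co-eluting ions from pairwise deltas.

    Pairs are matched against HCOOH attachment (+46.0055), HCl attachment
    (+35.9767) and dimerization (m2 = 2*m1 + proton). Every consistent
    hypothesis is reported, so an ambiguous ion carries several assignments;
    ions with no pairing default to [M-H]-.
    """
    if not coeluting_mzs:
        raise ValueError("need at least one m/z value")
    mzs = sorted(float(m) for m in coeluting_mzs)
    assignments: list[AdductAssignment] = []
    paired: set[float] = set()
    for i, m1 in enumerate(mzs):
        for m2 in mzs[i + 1:]:
            delta = m2 - m1
            for adduct, ref in _PAIR_DELTAS.items():
                if abs(delta - ref) <= tol:
                    assignments.append(
                        AdductAssignment(m1, Adduct.M_MINUS_H, m2, delta))
                    assignments.append(AdductAssignment(m2, adduct, m1, delta))
                    paired.update((m1, m2))
            dimer_delta = m2 - (2 * m1 + PROTON_MASS)
            if abs(dimer_delta) <= tol:
                assignments.append(
                    AdductAssignment(m1, Adduct.M_MINUS_H, m2, m2 - m1))
                assignments.append(
                    AdductAssignment(m2, Adduct.DIMER_MINUS_H, m1, m2 - m1))
                paired.update((m1, m2))
    for m in mzs:
        if m not in paired:
            assignments.append(AdductAssignment(m, Adduct.M_MINUS_H, None, None))
    return assignments


def neutral_losses(
    spectrum: MSnSpectrum,
    tol: float | None = None,
    library: dict[str, float] | None = None,
) -> list[NeutralLossHit]:
    """Match precursor-fragment mass differences against the loss library.

    Each stage of the tree is scanned independently (its own precursor against
    its own peaks). The tolerance tier follows the data precision unless a
    fixed ``tol`` is given. A delta consistent with more than one library
    entry (e.g. hexosyl vs caffeoyl at nominal resolution) yields one hit per
    consistent name, each flagged ambiguous.
    """
    if not any(True for _ in spectrum.all_peaks()):
        raise ValueError("spectrum has no peaks")
    library = library if library is not None else NEUTRAL_LOSS_LIBRARY
    hits: list[NeutralLossHit] = []
    for node in spectrum.walk():
        for peak in node.peaks:
            delta = node.precursor_mz - peak.mz
            if delta <= 0.5:  # self- or noise-level difference
                continue
            eff_tol = (
                tol if tol is not None
                else fragment_tolerance(node.precursor_mz, peak.mz)
            )
            matched = [
                (name, mass) for name, mass in library.items()
                if abs(delta - mass) <= eff_tol
            ]
            for name, mass in matched:
                hits.append(
                    NeutralLossHit(
                        loss_name=name,
                        library_mass=mass,
                        observed_delta=delta,
                        precursor_mz=node.precursor_mz,
                        fragment_mz=peak.mz,
                        ambiguous=len(matched) > 1,
                    )
                )
    return hits


def nearest_losses(
    spectrum: MSnSpectrum,
    tol: float | None = None,
    library: dict[str, float] | None = None,
) -> list[NeutralLossHit]:
    """Like :func:`neutral_losses` but each delta keeps only its nearest-mass
    library entry — the disambiguated view used by rule scoring."""
    hits = neutral_losses(spectrum, tol=tol, library=library)
    best: dict[tuple[float, float], NeutralLossHit] = {}
    for hit in hits:
        key = (hit.precursor_mz, hit.fragment_mz)
        if key not in best or abs(hit.delta) < abs(best[key].delta):
            best[key] = hit
    return [replace(h, ambiguous=False) for h in best.values()]
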