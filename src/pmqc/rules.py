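"""Diagnostic-ion searching: family classification, library annotation, and
crude-vs-processed profile comparison.

The strategy mirrors how an analyst screens high-resolution MS^n data for a
known herb: characteristic fragment ions (e.g. m/z 405.1177 / 243.0661 for
tetrahydroxystilbene glucosides, 269.0447 / 225.0544 / 241.0492 for
emodin-type anthraquinones) and supporting neutral losses (hexosyl, galloyl,
malonyl, ...) vote a feature into a chemical family; a retention-time and
precursor-mass match against the in-house library then upgrades the call to a
tentative or reference-standard identification.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .chem import (
    Adduct,
    ElementalFormula,
    FormulaCandidate,
    IonSpecies,
    enumerate_formulas,
    ion_mz,
    neutral_mass_from_mz,
    ppm_error,
)
from .spectra import (
    FRAGMENT_TOL_EXACT,
    FeatureRecord,
    MSnSpectrum,
    detect_adducts,
    fragment_tolerance,
    is_nominal,
    nearest_losses,
    read_peaklist,
)

__all__ = [
    "Confidence",
    "DiagnosticRule",
    "RuleBase",
    "CompoundEntry",
    "RuleEvidence",
    "AnnotationResult",
    "ProfileComparison",
    "load_default_rules",
    "load_rules",
    "load_table2_features",
    "load_table2_library",
    "match_diagnostic_ions",
    "classify_family",
    "annotate_feature",
    "annotate_features",
    "profile_compare",
    "write_annotation_tsv",
    "write_library_tsv",
]

FAMILIES = ("stilbene", "anthraquinone", "tannin", "naphthalene", "sugar", "unknown")

# Evidence points (see data/rules.yaml header for the model).
_POINTS_EXACT = 2
_POINTS_BASE_PEAK = 2
_POINTS_NOMINAL = 1
_DEFAULT_MIN_RELINT = 25.0


class Confidence(str, Enum):
    IDENTIFIED = "identified"     # library match against a reference standard
    TENTATIVE = "tentative"       # library match without a standard
    CLASS_ONLY = "class_only"     # diagnostic-rule family evidence only
    UNKNOWN = "unknown"

    @property
    def rank(self) -> int:
        order = [Confidence.UNKNOWN, Confidence.CLASS_ONLY,
                 Confidence.TENTATIVE, Confidence.IDENTIFIED]
        return order.index(self)


@dataclass(frozen=True)
class DiagnosticRule:
    """One family rule: diagnostic ions plus supporting neutral losses."""

    name: str
    family: str
    diagnostic_mzs: tuple[float, ...]
    supporting_losses: tuple[str, ...] = ()
    required_score: int = 2
    require_loss: bool = False
    odd_electron: bool = False
    min_relint: float = _DEFAULT_MIN_RELINT

    def __post_init__(self):
        if not self.diagnostic_mzs:
            raise ValueError("a rule needs at least one diagnostic m/z")
        if self.required_score < 1:
            raise ValueError("required_score must be >= 1")


@dataclass(frozen=True)
class RuleBase:
    rules: tuple[DiagnosticRule, ...]
    family_priority: tuple[str, ...]

    def priority_index(self, family: str) -> int:
        try:
            return self.family_priority.index(family)
        except ValueError:
            return len(self.family_priority)


@dataclass
class CompoundEntry:
    """One library compound mirroring an annotation-table row."""

    id: str
    name: str
    rt: float
    family: str
    ions: list[tuple[float, Adduct | None]]
    spectra: MSnSpectrum | None = None
    neutral_formula: ElementalFormula | None = None
    is_reference_standard: bool = False
    ppm_only: bool = False

    def __post_init__(self):
        if self.rt <= 0:
            raise ValueError("library retention time must be > 0")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class RuleEvidence:
    rule: DiagnosticRule
    score: float
    diagnostic_points: float
    exact_hits: int
    matched_peaks: list[tuple[float, float]]  # (diagnostic m/z, matched m/z)
    matched_losses: list[str]
    met: bool


@dataclass
class AnnotationResult:
    feature_id: str
    family: str
    confidence: Confidence
    matched_rules: list[RuleEvidence]
    formula_candidates: list[FormulaCandidate]
    matched_entry: CompoundEntry | None = None
    ambiguous_entries: list[CompoundEntry] = field(default_factory=list)
    precursor_mz: float | None = None
    adduct: Adduct | None = None
    precursor_ppm: float | None = None
    rt: float | None = None
    origin_flags: frozenset[str] = frozenset()

    @property
    def name(self) -> str:
        return self.matched_entry.name if self.matched_entry else ""

    @property
    def top_formula(self) -> FormulaCandidate | None:
        return self.formula_candidates[0] if self.formula_candidates else None

    @property
    def is_ambiguous(self) -> bool:
        return len(self.ambiguous_entries) > 1


# ---------------------------------------------------------------------------
# Rule-base and library loading


def _rule_from_obj(obj: Mapping) -> DiagnosticRule:
    return DiagnosticRule(
        name=str(obj["name"]),
        family=str(obj["family"]),
        diagnostic_mzs=tuple(float(m) for m in obj["diagnostic_mzs"]),
        supporting_losses=tuple(obj.get("supporting_losses", ())),
        required_score=int(obj.get("required_score", 2)),
        require_loss=bool(obj.get("require_loss", False)),
        odd_electron=bool(obj.get("odd_electron", False)),
        min_relint=float(obj.get("min_relint", _DEFAULT_MIN_RELINT)),
    )


def load_rules(path: str | Path) -> RuleBase:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return RuleBase(
        rules=tuple(_rule_from_obj(o) for o in doc["rules"]),
        family_priority=tuple(doc.get("family_priority", ())),
    )


def _data_path(name: str) -> Path:
    return Path(resources.files("pmqc.data").joinpath(name))  # type: ignore[arg-type]


def load_default_rules() -> RuleBase:
    return load_rules(_data_path("rules.yaml"))


def load_table2_features() -> list[FeatureRecord]:
    """The shipped 25-compound CPM/PPM annotation fixture."""
    return read_peaklist(_data_path("table2_features.json"), "json")


def library_from_features(records: Iterable[FeatureRecord]) -> list[CompoundEntry]:
    entries = []
    for rec in records:
        entries.append(
            CompoundEntry(
                id=rec.id,
                name=rec.name or rec.id,
                rt=rec.rt,
                family=rec.family or "unknown",
                ions=list(rec.precursor_ions),
                spectra=rec.spectra,
                neutral_formula=(
                    ElementalFormula.parse(rec.neutral_formula)
                    if rec.neutral_formula else None
                ),
                is_reference_standard=rec.is_reference_standard,
                ppm_only=rec.origin_flags == frozenset({"PPM"}),
            )
        )
    return entries


def load_table2_library() -> list[CompoundEntry]:
    return library_from_features(load_table2_features())


def write_library_tsv(entries: Sequence[CompoundEntry], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["id", "name", "rt_min", "family", "ions", "neutral_formula",
             "standard", "ppm_only"]
        )
        for e in entries:
            ions = ";".join(
                f"{mz}{'[' + ad.value + ']' if ad else ''}" for mz, ad in e.ions
            )
            writer.writerow(
                [e.id, e.name, e.rt, e.family, ions,
                 str(e.neutral_formula or ""),
                 int(e.is_reference_standard), int(e.ppm_only)]
            )


# ---------------------------------------------------------------------------
# Evidence scoring


def _diagnostic_candidates(
    feature: FeatureRecord,
) -> list[tuple[float, float, bool]]:
    """(m/z, relative intensity, is_high_res) for every ion in the tree."""
    cands = [(mz, 100.0, True) for mz, _ in feature.precursor_ions]
    if feature.spectra is not None:
        for _node, peak in feature.spectra.all_peaks():
            cands.append((peak.mz, peak.relative_intensity, not peak.is_nominal))
    return cands


def _diagnostic_points(
    diag_mz: float,
    candidates: Sequence[tuple[float, float, bool]],
    min_relint: float,
) -> tuple[float, bool, float | None]:
    """Best score for one diagnostic ion: (points, exact?, matched m/z)."""
    best = (0.0, False, None)
    diag_hi_res = not is_nominal(diag_mz)
    for mz, relint, hi_res in candidates:
        exact_tier = diag_hi_res and hi_res
        tol = FRAGMENT_TOL_EXACT if exact_tier else fragment_tolerance(diag_mz, mz)
        if abs(mz - diag_mz) > tol:
            continue
        if exact_tier:
            points, exact = _POINTS_EXACT, True
        elif relint >= 100.0 - 1e-9:
            points, exact = _POINTS_BASE_PEAK, False
        elif relint >= min_relint:
            points, exact = _POINTS_NOMINAL, False
        else:
            continue
        if (points, exact) > (best[0], best[1]):
            best = (points, exact, mz)
    return best


def match_diagnostic_ions(
    feature: FeatureRecord, rules: RuleBase | Sequence[DiagnosticRule]
) -> list[RuleEvidence]:
    """Score every rule against a feature's full MS^n tree.

    Diagnostic ions are searched among the precursor ions and all fragment
    peaks at every stage; supporting losses use the disambiguated
    (nearest-name) neutral-loss view. A rule is met when at least one
    diagnostic ion matched and the total score reaches the rule's threshold.
    """
    rule_list = rules.rules if isinstance(rules, RuleBase) else tuple(rules)
    candidates = _diagnostic_candidates(feature)
    loss_names: set[str] = set()
    if feature.spectra is not None and feature.spectra.peaks:
        loss_names = {h.loss_name for h in nearest_losses(feature.spectra)}

    out = []
    for rule in rule_list:
        diag_points = 0.0
        exact_hits = 0
        matched_peaks = []
        for diag in rule.diagnostic_mzs:
            points, exact, matched_mz = _diagnostic_points(
                diag, candidates, rule.min_relint
            )
            if points > 0:
                diag_points += points
                exact_hits += int(exact)
                matched_peaks.append((diag, matched_mz))
        matched_losses = sorted(loss_names & set(rule.supporting_losses))
        score = diag_points + len(matched_losses)
        met = (
            diag_points >= 1
            and score >= rule.required_score
            and (not rule.require_loss or bool(matched_losses))
        )
        out.append(
            RuleEvidence(
                rule=rule,
                score=score,
                diagnostic_points=diag_points,
                exact_hits=exact_hits,
                matched_peaks=matched_peaks,
                matched_losses=matched_losses,
                met=met,
            )
        )
    return out


def classify_family(
    feature: FeatureRecord, rules: RuleBase | None = None
) -> str:
    """Family with the highest met-rule evidence; "unknown" when none fires.

    Ties break on more exact-mass diagnostic hits, then on the configured
    family priority order.
    """
    rules = rules if rules is not None else load_default_rules()
    evidence = [e for e in match_diagnostic_ions(feature, rules) if e.met]
    if not evidence:
        return "unknown"
    per_family: dict[str, tuple[float, int]] = {}
    for ev in evidence:
        score, exact = per_family.get(ev.rule.family, (0.0, 0))
        per_family[ev.rule.family] = (max(score, ev.score), max(exact, ev.exact_hits))
    return min(
        per_family,
        key=lambda fam: (
            -per_family[fam][0],
            -per_family[fam][1],
            rules.priority_index(fam),
        ),
    )


# ---------------------------------------------------------------------------
# Library annotation


def _resolve_adducts(feature: FeatureRecord) -> list[tuple[float, Adduct]]:
    """Fill unlabelled precursor ions via co-occurrence detection."""
    if all(ad is not None for _, ad in feature.precursor_ions):
        return [(mz, ad) for mz, ad in feature.precursor_ions]  # type: ignore
    assignments = detect_adducts([mz for mz, _ in feature.precursor_ions])
    by_mz: dict[float, Adduct] = {}
    for a in assignments:
        by_mz.setdefault(a.mz, a.adduct)
    return [
        (mz, ad if ad is not None else by_mz.get(mz, Adduct.M_MINUS_H))
        for mz, ad in feature.precursor_ions
    ]


def _shared_fragment(
    feature: FeatureRecord, entry: CompoundEntry
) -> bool:
    if feature.spectra is None or entry.spectra is None:
        return False
    feat_peaks = [p.mz for _, p in feature.spectra.all_peaks()]
    lib_peaks = [p.mz for _, p in entry.spectra.all_peaks()]
    return any(
        abs(a - b) <= fragment_tolerance(a, b)
        for a in feat_peaks for b in lib_peaks
    )


def annotate_feature(
    feature: FeatureRecord,
    library: Sequence[CompoundEntry],
    rules: RuleBase | None = None,
    tol_ppm: float = 5.0,
    rt_window: float = 0.2,
) -> AnnotationResult:
    """Full annotation of one feature.

    1. Adduct-corrected precursor -> CHO formula candidates within tol_ppm.
    2. Library match: precursor within tol_ppm of an entry ion, retention
       time within rt_window, and at least one shared fragment peak. Several
       passing entries are all reported and the result flagged ambiguous.
    3. Confidence ladder: identified (standard) > tentative (library) >
       class_only (rule evidence) > unknown.
    """
    rules = rules if rules is not None else load_default_rules()
    ions = _resolve_adducts(feature)
    mz0, adduct0 = ions[0]
    for mz, ad in ions:
        if ad is Adduct.M_MINUS_H:
            mz0, adduct0 = mz, ad
            break
    neutral = neutral_mass_from_mz(mz0, adduct0)
    candidates = enumerate_formulas(neutral, tol_ppm=tol_ppm)

    matches: list[tuple[float, CompoundEntry]] = []
    for entry in library:
        if abs(feature.rt - entry.rt) > rt_window:
            continue
        # reference m/z per entry ion: theoretical adduct mass when the
        # composition is known, else the recorded observation
        ref_mzs = [
            ion_mz(IonSpecies(entry.neutral_formula, ead))
            if entry.neutral_formula is not None and ead is not None
            else emz
            for emz, ead in entry.ions
        ]
        best_ppm = None
        for fmz, _ in feature.precursor_ions:
            for emz in ref_mzs:
                err = ppm_error(fmz, emz)
                if abs(err) <= tol_ppm and (
                    best_ppm is None or abs(err) < abs(best_ppm)
                ):
                    best_ppm = err
        if best_ppm is None:
            continue
        if not _shared_fragment(feature, entry):
            continue
        matches.append((best_ppm, entry))
    matches.sort(key=lambda t: (abs(t[0]), t[1].id))

    evidence = match_diagnostic_ions(feature, rules)
    met = [e for e in evidence if e.met]
    rule_family = classify_family(feature, rules)

    if matches:
        best_ppm, best_entry = matches[0]
        confidence = (
            Confidence.IDENTIFIED
            if best_entry.is_reference_standard
            else Confidence.TENTATIVE
        )
        family = best_entry.family
    else:
        best_ppm, best_entry = None, None
        confidence = Confidence.CLASS_ONLY if met else Confidence.UNKNOWN
        family = rule_family

    return AnnotationResult(
        feature_id=feature.id,
        family=family,
        confidence=confidence,
        matched_rules=met,
        formula_candidates=candidates,
        matched_entry=best_entry,
        ambiguous_entries=[e for _, e in matches],
        precursor_mz=mz0,
        adduct=adduct0,
        precursor_ppm=best_ppm,
        rt=feature.rt,
        origin_flags=feature.origin_flags,
    )


def annotate_features(
    features: Iterable[FeatureRecord],
    library: Sequence[CompoundEntry] | None = None,
    rules: RuleBase | None = None,
    tol_ppm: float = 5.0,
    rt_window: float = 0.2,
) -> list[AnnotationResult]:
    library = library if library is not None else load_table2_library()
    rules = rules if rules is not None else load_default_rules()
    return [
        annotate_feature(f, library, rules, tol_ppm=tol_ppm, rt_window=rt_window)
        for f in features
    ]


# ---------------------------------------------------------------------------
# Profile comparison


@dataclass
class ProfileComparison:
    presence: dict[str, dict[str, bool]]  # compound label -> group -> present
    groups: tuple[str, ...]
    total_annotated: int
    phenolic_annotated: int               # non-sugar compounds
    exclusive_counts: dict[str, int]      # group -> detected only there

    def exclusive(self, group: str) -> list[str]:
        return sorted(
            label
            for label, flags in self.presence.items()
            if flags.get(group) and not any(
                v for g, v in flags.items() if g != group
            )
        )


def profile_compare(
    annotations_by_group: Mapping[str, Sequence[AnnotationResult]],
) -> ProfileComparison:
    """Presence/absence table and summary counts across sample groups.

    A compound's label is its matched library id when available, else the
    feature id. "Phenolic" counts every annotated compound outside the sugar
    family (primary metabolites are excluded from the phenolic profile).
    """
    if not annotations_by_group:
        raise ValueError("need at least one sample group")
    groups = tuple(annotations_by_group)
    presence: dict[str, dict[str, bool]] = {}
    families: dict[str, str] = {}
    for group, annos in annotations_by_group.items():
        for anno in annos:
            label = anno.matched_entry.id if anno.matched_entry else anno.feature_id
            presence.setdefault(label, {g: False for g in groups})[group] = True
            families[label] = anno.family
    exclusive_counts = {
        g: sum(
            1
            for flags in presence.values()
            if flags.get(g) and not any(v for gg, v in flags.items() if gg != g)
        )
        for g in groups
    }
    total = len(presence)
    phenolic = sum(1 for label in presence if families.get(label) != "sugar")
    return ProfileComparison(
        presence=presence,
        groups=groups,
        total_annotated=total,
        phenolic_annotated=phenolic,
        exclusive_counts=exclusive_counts,
    )


def write_annotation_tsv(
    annotations: Sequence[AnnotationResult], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["id", "rt", "precursor_mz", "adduct", "top_formula", "ppm",
             "family", "confidence", "name", "evidence"]
        )
        for a in annotations:
            top = a.top_formula
            evidence = ";".join(
                f"{e.rule.name}(score={e.score:g})" for e in a.matched_rules
            )
            writer.writerow(
                [
                    a.feature_id,
                    f"{a.rt:.2f}" if a.rt is not None else "",
                    f"{a.precursor_mz:.4f}" if a.precursor_mz is not None else "",
                    a.adduct.value if a.adduct else "",
                    str(top.formula) if top else "",
                    f"{top.ppm_error:.2f}" if top else "",
                    a.family,
                    a.confidence.value,
                    a.name,
                    evidence,
                ]
            )
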