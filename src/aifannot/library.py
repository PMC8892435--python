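"""Fragment libraries of parent and fragment ions with occurrence scores.

A library is a collection of records, one per (metabolite, adduct) pair.
Each record carries the parent adduct m/z and a list of expected fragment
m/z values; every ion has an occurrence score ``s`` >= 0 weighting how
likely that ion is to be observed. Libraries are stored as CSV files, one
file per (metabolite class, adduct) combination, and can be imported from
NIST-style MSP/txt spectral files or generated for lipid classes from
chain-composition templates.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

__all__ = [
    "LibraryFragment",
    "LibraryRecord",
    "Library",
    "LibraryError",
    "load_library",
    "write_library",
    "import_msp",
    "LipidClassTemplate",
    "expand_lipid_class",
    "monoisotopic_mass",
    "ADDUCT_MASS_SHIFT",
    "PROTON_MASS",
]

logger = logging.getLogger(__name__)

#: CSV column order of the library dialect (one row per ion).
CSV_COLUMNS = ["name", "adduct", "polarity", "ion_type", "mz", "occurrence_score", "label"]

DEFAULT_PARENT_SCORE = 1.0
DEFAULT_FRAGMENT_SCORE = 0.5

PROTON_MASS = 1.007276466

#: Monoisotopic atomic masses (u) of the elements needed for small-molecule
#: and lipid ion formulas.
ATOMIC_MASS = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
    "F": 18.99840322,
}

#: m/z shift from neutral monoisotopic mass for common singly charged adducts.
ADDUCT_MASS_SHIFT = {
    "[M+H]+": PROTON_MASS,
    "[M+Na]+": ATOMIC_MASS["Na"] - (ATOMIC_MASS["H"] - PROTON_MASS),
    "[M+K]+": ATOMIC_MASS["K"] - (ATOMIC_MASS["H"] - PROTON_MASS),
    "[M+NH4]+": ATOMIC_MASS["N"] + 4 * ATOMIC_MASS["H"] + PROTON_MASS - ATOMIC_MASS["H"],
    "[M-H]-": -PROTON_MASS,
    "[M+Cl]-": ATOMIC_MASS["Cl"] + (ATOMIC_MASS["H"] - PROTON_MASS),
}


class LibraryError(ValueError):
    """Fatal library I/O or validation error."""


def _parse_formula(formula: str) -> dict[str, int]:
    tokens = re.findall(r"([A-Z][a-z]?)(\d*)", formula)
    counts: dict[str, int] = {}
    consumed = 0
    for elem, num in tokens:
        if not elem:
            continue
        if elem not in ATOMIC_MASS:
            raise LibraryError(f"unknown element {elem!r} in formula {formula!r}")
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
        consumed += len(elem) + len(num)
    if consumed != len(formula):
        raise LibraryError(f"could not parse formula {formula!r}")
    return counts


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass (u) of a neutral molecular formula such as ``C5H14NO4P``."""
    return sum(ATOMIC_MASS[e] * n for e, n in _parse_formula(formula).items())


# anion adducts: neutral formula mass plus the electron gained on ionization
_ELECTRON = ATOMIC_MASS["H"] - PROTON_MASS
ADDUCT_MASS_SHIFT["[M+HCOO]-"] = monoisotopic_mass("CHO2") + _ELECTRON
ADDUCT_MASS_SHIFT["[M+CH3COO]-"] = monoisotopic_mass("C2H3O2") + _ELECTRON


def adduct_polarity(adduct: str) -> str | None:
    """Infer ionization polarity from an adduct token ending in '+' or '-'."""
    token = adduct.strip()
    if token.endswith("+"):
        return "positive"
    if token.endswith("-"):
        return "negative"
    return None


@dataclass(frozen=True)
class LibraryFragment:
    """A single expected fragment ion with its occurrence score."""

    mz: float
    occurrence_score: float = DEFAULT_FRAGMENT_SCORE
    label: str = ""

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise LibraryError(f"fragment mz must be positive, got {self.mz}")
        if not self.occurrence_score >= 0:
            raise LibraryError(f"occurrence score must be >= 0, got {self.occurrence_score}")


@dataclass
class LibraryRecord:
    """One (metabolite, adduct) library entry: parent ion plus fragments."""

    metabolite_name: str
    adduct: str
    polarity: str
    parent_mz: float
    parent_occurrence_score: float = DEFAULT_PARENT_SCORE
    fragments: list[LibraryFragment] = field(default_factory=list)
    source_file: str = ""

    def __post_init__(self) -> None:
        if not self.parent_mz > 0:
            raise LibraryError(f"parent mz must be positive, got {self.parent_mz}")
        if self.polarity not in ("positive", "negative"):
            raise LibraryError(f"polarity must be positive|negative, got {self.polarity!r}")
        inferred = adduct_polarity(self.adduct)
        if inferred is not None and inferred != self.polarity:
            raise LibraryError(
                f"adduct {self.adduct!r} inconsistent with polarity {self.polarity!r}"
            )
        seen: set[float] = set()
        for frag in self.fragments:
            key = round(frag.mz, 4)
            if key in seen:
                raise LibraryError(
                    f"duplicate fragment m/z {frag.mz:.4f} in record {self.metabolite_name!r}"
                )
            seen.add(key)

    @property
    def ion_mzs(self) -> list[float]:
        """Parent m/z followed by all fragment m/z values."""
        return [self.parent_mz] + [f.mz for f in self.fragments]

    def class_key(self) -> tuple[str, str]:
        """Grouping key (metabolite class, adduct) used for one-file-per-group CSV output.

        The class is the prefix before the first '(' of the metabolite name
        (e.g. ``PC(34:1)`` -> ``PC``), or the full name when no parenthesis.
        """
        name = self.metabolite_name.split("(", 1)[0].strip() or self.metabolite_name
        return (name, self.adduct)


@dataclass
class Library:
    """A collection of library records of one ionization polarity."""

    records: list[LibraryRecord]
    polarity: str
    source_files: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.polarity != self.polarity:
                raise LibraryError(
                    f"record {rec.metabolite_name!r} polarity {rec.polarity!r} "
                    f"differs from library polarity {self.polarity!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _record_sort_key(rec: LibraryRecord):
    return (rec.metabolite_name, rec.adduct, rec.parent_mz)


def load_library(directory: str | Path, polarity: str) -> Library:
    """Load all library CSV files of the given polarity from a directory.

    Malformed rows are skipped with a logged warning; files contributing no
    valid record are ignored. Raises :class:`LibraryError` if the directory
    is missing or yields zero parseable records.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise LibraryError(f"library directory not found: {directory}")
    records: list[LibraryRecord] = []
    sources: list[str] = []
    n_warnings = 0
    for path in sorted(directory.glob("*.csv")):
        file_records, file_warnings = _read_library_csv(path, polarity)
        n_warnings += file_warnings
        if file_records:
            records.extend(file_records)
            sources.append(str(path))
    if not records:
        raise LibraryError(f"no parseable {polarity}-mode library records in {directory}")
    if n_warnings:
        logger.warning("skipped %d malformed library rows in %s", n_warnings, directory)
    records.sort(key=_record_sort_key)
    lib = Library(records=records, polarity=polarity, source_files=sources)
    logger.info("loaded %d %s-mode records from %s", len(records), polarity, directory)
    return lib


def _read_library_csv(path: Path, polarity: str) -> tuple[list[LibraryRecord], int]:
    """Parse one library CSV; returns (records of matching polarity, warning count)."""
    n_warnings = 0
    # rows grouped by (name, adduct); parent row defines the record
    groups: dict[tuple[str, str], dict] = {}
    order: list[tuple[str, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "mz" not in reader.fieldnames:
            logger.warning("file %s lacks the library CSV header; skipped", path)
            return [], 1
        for lineno, row in enumerate(reader, start=2):
            try:
                name = (row.get("name") or "").strip()
                adduct = (row.get("adduct") or "").strip()
                row_pol = (row.get("polarity") or "").strip().lower()
                ion_type = (row.get("ion_type") or "").strip().lower()
                mz = float(row["mz"])
                score_raw = (row.get("occurrence_score") or "").strip()
                label = (row.get("label") or "").strip()
                if not name or not adduct or ion_type not in ("parent", "fragment"):
                    raise ValueError("missing name/adduct/ion_type")
                if mz <= 0:
                    raise ValueError("non-positive mz")
            except (ValueError, KeyError, TypeError) as exc:
                logger.warning("%s:%d malformed row skipped (%s)", path, lineno, exc)
                n_warnings += 1
                continue
            if row_pol and row_pol != polarity:
                continue
            key = (name, adduct)
            if key not in groups:
                groups[key] = {"parent": None, "fragments": []}
                order.append(key)
            if ion_type == "parent":
                score = float(score_raw) if score_raw else DEFAULT_PARENT_SCORE
                groups[key]["parent"] = (mz, score, label)
            else:
                score = float(score_raw) if score_raw else DEFAULT_FRAGMENT_SCORE
                groups[key]["fragments"].append(LibraryFragment(mz, score, label))
    records: list[LibraryRecord] = []
    for name, adduct in order:
        grp = groups[(name, adduct)]
        if grp["parent"] is None:
            logger.warning("%s: record %r/%r has no parent row; skipped", path, name, adduct)
            n_warnings += 1
            continue
        pmz, pscore, _ = grp["parent"]
        try:
            records.append(
                LibraryRecord(
                    metabolite_name=name,
                    adduct=adduct,
                    polarity=polarity,
                    parent_mz=pmz,
                    parent_occurrence_score=pscore,
                    fragments=grp["fragments"],
                    source_file=str(path),
                )
            )
        except LibraryError as exc:
            logger.warning("%s: record %r/%r invalid (%s); skipped", path, name, adduct, exc)
            n_warnings += 1
    return records, n_warnings


def _safe_token(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]+", "_", text).strip("_") or "x"


def write_library(lib: Library, directory: str | Path) -> list[Path]:
    """Write a library as one CSV per (metabolite class, adduct) group.

    The output is losslessly re-loadable with :func:`load_library`.
    """
    if not lib.records:
        raise LibraryError("cannot write an empty library")
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise LibraryError(f"cannot create library directory {directory}: {exc}") from exc
    groups: dict[tuple[str, str], list[LibraryRecord]] = {}
    for rec in lib.records:
        groups.setdefault(rec.class_key(), []).append(rec)
    written: list[Path] = []
    for (cls, adduct), recs in sorted(groups.items()):
        path = directory / f"{_safe_token(cls)}_{_safe_token(adduct)}.csv"
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_COLUMNS)
            for rec in sorted(recs, key=_record_sort_key):
                writer.writerow(
                    [rec.metabolite_name, rec.adduct, rec.polarity, "parent",
                     repr(rec.parent_mz), repr(rec.parent_occurrence_score), ""]
                )
                for frag in rec.fragments:
                    writer.writerow(
                        [rec.metabolite_name, rec.adduct, rec.polarity, "fragment",
                         repr(frag.mz), repr(frag.occurrence_score), frag.label]
                    )
        written.append(path)
    return written


_MSP_PRECURSOR_KEYS = ("precursormz", "precursor_mz", "precursor m/z", "precursor")
_MSP_PEAK_RE = re.compile(r"^\s*(\d+\.?\d*(?:[eE][+-]?\d+)?)[\s,;]+(\d+\.?\d*(?:[eE][+-]?\d+)?)")


def import_msp(
    file: str | Path,
    polarity: str,
    default_occurrence: float = DEFAULT_FRAGMENT_SCORE,
) -> Library:
    """Import a NIST-style MSP (or equivalent .txt) spectral file as a library.

    One record is created per ``NAME:`` block that carries a precursor m/z;
    the precursor becomes the parent ion and every listed peak becomes a
    fragment with ``occurrence_score = default_occurrence``. Entries without
    a precursor are skipped with a warning.
    """
    file = Path(file)
    if not file.is_file():
        raise LibraryError(f"MSP file not found: {file}")
    records: list[LibraryRecord] = []
    current: dict | None = None

    def _flush(entry: dict | None) -> None:
        if entry is None:
            return
        if entry.get("precursor") is None:
            logger.warning("MSP entry %r has no precursor m/z; skipped", entry.get("name"))
            return
        frags = [
            LibraryFragment(mz, default_occurrence, "")
            for mz in entry["peaks"]
            if mz > 0
        ]
        # collapse duplicate fragment m/z (to 4 dp) keeping first occurrence
        seen: set[float] = set()
        unique = []
        for f in frags:
            key = round(f.mz, 4)
            if key not in seen:
                seen.add(key)
                unique.append(f)
        records.append(
            LibraryRecord(
                metabolite_name=entry["name"],
                adduct=entry.get("adduct", ""),
                polarity=polarity,
                parent_mz=entry["precursor"],
                parent_occurrence_score=DEFAULT_PARENT_SCORE,
                fragments=unique,
                source_file=str(file),
            )
        )

    with open(file, encoding="utf-8", errors="replace") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if ":" in line and not _MSP_PEAK_RE.match(line):
                key, _, value = line.partition(":")
                key = key.strip().lower()
                value = value.strip()
                if key == "name":
                    _flush(current)
                    current = {"name": value, "precursor": None, "peaks": []}
                elif current is not None and key in _MSP_PRECURSOR_KEYS:
                    try:
                        current["precursor"] = float(value)
                    except ValueError:
                        pass
                elif current is not None and key in ("precursortype", "precursor_type", "adduct"):
                    current["adduct"] = value
                continue
            m = _MSP_PEAK_RE.match(line)
            if m and current is not None:
                current["peaks"].append(float(m.group(1)))
    _flush(current)
    if not records:
        raise LibraryError(f"no importable MSP entries in {file}")
    return Library(records=records, polarity=polarity, source_files=[str(file)])


# mass added per acyl-chain carbon (CH2) and removed per double bond (H2)
CH2_MASS = ATOMIC_MASS["C"] + 2 * ATOMIC_MASS["H"]
H2_MASS = 2 * ATOMIC_MASS["H"]


@dataclass
class LipidClassTemplate:
    """Template generating theoretical parent/fragment m/z for one lipid class.

    ``base_formula`` is the neutral formula of the class scaffold with zero
    acyl-chain carbons and zero double bonds; each chain carbon adds CH2 and
    each double bond removes H2. ``fragment_rules`` map (carbons,
    double_bonds, parent_mz) to a fragment m/z, with a label and occurrence
    score each; rules returning None for a combination are skipped.
    """

    class_name: str
    base_formula: str
    fragment_rules: list[tuple[str, Callable[[int, int, float], float | None], float]] = field(
        default_factory=list
    )

    def neutral_mass(self, carbons: int, double_bonds: int) -> float:
        return (
            monoisotopic_mass(self.base_formula)
            + carbons * CH2_MASS
            - double_bonds * H2_MASS
        )

    def species_name(self, carbons: int, double_bonds: int) -> str:
        return f"{self.class_name}({carbons}:{double_bonds})"


def expand_lipid_class(
    template: LipidClassTemplate,
    chain_space: Sequence[tuple[int, int]],
    adducts: Iterable[str],
) -> Library:
    """Expand a lipid-class template over chain compositions and adducts.

    Returns one record per (chain composition, adduct); all m/z values are
    computed from monoisotopic atomic masses. All adducts must share one
    polarity.
    """
    adducts = list(adducts)
    if not adducts:
        raise LibraryError("no adducts given")
    polarities = {adduct_polarity(a) for a in adducts}
    if None in polarities or len(polarities) != 1:
        raise LibraryError(f"adducts {adducts} must share a recognizable polarity")
    polarity = polarities.pop()
    records: list[LibraryRecord] = []
    for carbons, double_bonds in chain_space:
        if carbons < 0 or double_bonds < 0:
            raise LibraryError(
                f"negative chain composition ({carbons},{double_bonds})"
            )
        neutral = template.neutral_mass(carbons, double_bonds)
        for adduct in adducts:
            if adduct not in ADDUCT_MASS_SHIFT:
                raise LibraryError(f"unknown adduct {adduct!r}")
            parent_mz = neutral + ADDUCT_MASS_SHIFT[adduct]
            frags = []
            seen: set[float] = set()
            for label, rule, score in template.fragment_rules:
                mz = rule(carbons, double_bonds, parent_mz)
                if mz is None or mz <= 0:
                    continue
                key = round(mz, 4)
                if key in seen:
                    continue
                seen.add(key)
                frags.append(LibraryFragment(mz, score, label))
            records.append(
                LibraryRecord(
                    metabolite_name=template.species_name(carbons, double_bonds),
                    adduct=adduct,
                    polarity=polarity,
                    parent_mz=parent_mz,
                    parent_occurrence_score=DEFAULT_PARENT_SCORE,
                    fragments=frags,
                    source_file=f"template:{template.class_name}",
                )
            )
    return Library(records=records, polarity=polarity,
                   source_files=[f"template:{template.class_name}"])
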