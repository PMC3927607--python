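"""Tabular I/O and SCOP concise-classification-string (css) parsing.

The pipeline consumes three tab-separated inputs:

* ``assignments.tsv`` — one HMM domain assignment per row
  (``genome_id  protein_id  css  region  evalue``); ``#`` lines are comments.
* ``annotation.tsv`` — the two-tier FSF→(minor, general) functional scheme
  (``fsf_key  minor_category  general_category``); FSFs without a functional
  annotation carry the reserved minor label ``NONA``.
* ``genomes.tsv`` — per-genome metadata
  (``genome_id  superkingdom  group  lifestyle``).

A css such as ``c.26.1.2`` encodes SCOP class (``c``), fold (26), fold
superfamily (FSF, 1) and fold family (FF, 2); the census operates at FSF
level, so the canonical key of any css is its first three tokens
(``c.26.1``).

The packaged default annotation scheme reproduces the published SCOP 1.73
SUPERFAMILY category sizes (7 general categories, 49 annotated minor
categories plus NONA, 1,646 annotated FSFs + 135 NONA = 1,781). Because the
FSF identities behind those counts are not distributed, the packaged scheme
expands the count table into deterministic synthetic placeholder keys; a
scheme with real keys can be supplied via :func:`read_annotation_scheme`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

logger = logging.getLogger("fsfcensus")

# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------


class FsfCensusError(Exception):
    """Base class for all errors raised by fsfcensus."""


class CssParseError(FsfCensusError, ValueError):
    """A concise classification string could not be parsed."""


class FormatError(FsfCensusError, ValueError):
    """A tabular input file violates its format contract."""


class ValidationError(FsfCensusError, ValueError):
    """A record or scheme violates a domain invariant."""


# --------------------------------------------------------------------------
# Category vocabulary
# --------------------------------------------------------------------------

#: The seven general functional categories, in published table order.
GENERAL_CATEGORIES: tuple[str, ...] = (
    "Metabolism",
    "General",
    "Information",
    "Other",
    "Extracellular processes",
    "Intracellular processes",
    "Regulation",
)

#: Reserved label for FSFs without a functional annotation.
NONA = "NONA"

SUPERKINGDOMS = frozenset({"Archaea", "Bacteria", "Eukarya"})
LIFESTYLES = frozenset({"FL", "P", "OP", "unknown"})


def _norm(label: str) -> str:
    """Whitespace-collapsed, lowercased form used for category matching."""
    return " ".join(label.split()).lower()


_GENERAL_BY_NORM = {_norm(c): c for c in GENERAL_CATEGORIES}


def canonical_general(label: str) -> str:
    """Map a general-category label to its canonical spelling.

    Matching is case-insensitive after whitespace normalization. Raises
    :class:`ValidationError` for labels outside the closed 7-category set.
    """
    try:
        return _GENERAL_BY_NORM[_norm(label)]
    except KeyError:
        raise ValidationError(
            f"unknown general category {label!r}; expected one of "
            f"{', '.join(GENERAL_CATEGORIES)}"
        ) from None


# --------------------------------------------------------------------------
# css identifiers
# --------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class CssIdentifier:
    """A SCOP concise classification string at FSF or FF resolution."""

    scop_class: str
    fold_num: int
    fsf_num: int
    family_num: int | None = None

    def __post_init__(self) -> None:
        if not (
            len(self.scop_class) == 1
            and self.scop_class.isalpha()
            and self.scop_class.islower()
        ):
            raise CssParseError(
                f"scop_class must be a single lowercase letter, got {self.scop_class!r}"
            )
        for name in ("fold_num", "fsf_num"):
            if getattr(self, name) < 1:
                raise CssParseError(f"{name} must be a positive integer")
        if self.family_num is not None and self.family_num < 1:
            raise CssParseError("family_num must be a positive integer when present")

    @property
    def fsf_key(self) -> str:
        """Canonical FSF-level key, e.g. ``c.26.1`` for ``c.26.1.2``."""
        return f"{self.scop_class}.{self.fold_num}.{self.fsf_num}"

    def render(self) -> str:
        if self.family_num is None:
            return self.fsf_key
        return f"{self.fsf_key}.{self.family_num}"

    def __str__(self) -> str:  # pragma: no cover - delegates
        return self.render()


def parse_css(text: str) -> CssIdentifier:
    """Parse a css like ``c.26.1.2`` (FF level) or ``c.37.1`` (FSF level)."""
    if not isinstance(text, str) or not text.strip():
        raise CssParseError(f"empty css string: {text!r}")
    tokens = text.strip().split(".")
    if len(tokens) not in (3, 4):
        raise CssParseError(
            f"css {text!r} has {len(tokens)} dot-separated tokens; expected 3 or 4"
        )
    cls = tokens[0]
    nums = []
    for tok in tokens[1:]:
        if not re.fullmatch(r"\d+", tok):
            raise CssParseError(f"css {text!r}: non-integer field {tok!r}")
        nums.append(int(tok))
    try:
        return CssIdentifier(cls, nums[0], nums[1], nums[2] if len(nums) == 3 else None)
    except CssParseError as exc:
        raise CssParseError(f"css {text!r}: {exc}") from None


# --------------------------------------------------------------------------
# Records
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AssignmentRecord:
    """One HMM-assigned domain region on one protein of one genome."""

    genome_id: str
    protein_id: str
    css: CssIdentifier
    region: tuple[tuple[int, int], ...]
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError(
                f"negative E-value {self.evalue} on {self.genome_id}/{self.protein_id}"
            )
        for start, end in self.region:
            if start > end:
                raise ValidationError(
                    f"region start {start} > end {end} on "
                    f"{self.genome_id}/{self.protein_id}"
                )

    @property
    def fsf_key(self) -> str:
        return self.css.fsf_key


@dataclass(frozen=True)
class GenomeRecord:
    """Metadata for one genome: superkingdom, phylum/kingdom group, lifestyle."""

    genome_id: str
    superkingdom: str
    group: str
    lifestyle: str

    def __post_init__(self) -> None:
        if self.superkingdom not in SUPERKINGDOMS:
            raise ValidationError(
                f"genome {self.genome_id!r}: unknown superkingdom "
                f"{self.superkingdom!r} (expected Archaea/Bacteria/Eukarya)"
            )
        if self.lifestyle not in LIFESTYLES:
            raise ValidationError(
                f"genome {self.genome_id!r}: unknown lifestyle {self.lifestyle!r} "
                f"(expected FL/P/OP/unknown)"
            )


# --------------------------------------------------------------------------
# Annotation scheme
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationScheme:
    """Two-tier FSF → minor category → general category mapping.

    ``fsf_to_minor`` may map keys to the reserved ``NONA`` label; those keys
    are carried but excluded from every profile and pool statistic.
    ``minor_to_general`` covers annotated minors only.
    """

    minor_to_general: dict[str, str]
    fsf_to_minor: dict[str, str]
    minor_order: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.minor_to_general:
            raise ValidationError("empty annotation scheme")
        for minor, general in self.minor_to_general.items():
            if minor == NONA:
                raise ValidationError("NONA is reserved and cannot be a scheme minor")
            canonical_general(general)  # raises for labels outside the 7
        for key, minor in self.fsf_to_minor.items():
            if minor != NONA and minor not in self.minor_to_general:
                raise ValidationError(
                    f"FSF {key!r} mapped to unknown minor category {minor!r}"
                )
        if not self.minor_order:
            object.__setattr__(self, "minor_order", tuple(self.minor_to_general))

    # -- category views ----------------------------------------------------

    @property
    def general_categories(self) -> tuple[str, ...]:
        """General categories present, in published table order."""
        present = set(self.minor_to_general.values())
        return tuple(c for c in GENERAL_CATEGORIES if c in present)

    @property
    def minor_categories(self) -> tuple[str, ...]:
        """Annotated minor categories (NONA excluded), in scheme order."""
        return self.minor_order

    # -- lookups -----------------------------------------------------------

    def minor_of(self, fsf_key: str) -> str:
        """Minor category of an FSF key; unknown keys fall back to NONA."""
        return self.fsf_to_minor.get(fsf_key, NONA)

    def general_of(self, fsf_key: str) -> str:
        minor = self.minor_of(fsf_key)
        return NONA if minor == NONA else self.minor_to_general[minor]

    def is_annotated(self, fsf_key: str) -> bool:
        return self.minor_of(fsf_key) != NONA

    @property
    def annotated_fsfs(self) -> tuple[str, ...]:
        return tuple(k for k, m in self.fsf_to_minor.items() if m != NONA)

    @property
    def nona_fsfs(self) -> tuple[str, ...]:
        return tuple(k for k, m in self.fsf_to_minor.items() if m == NONA)

    def minor_sizes(self) -> dict[str, int]:
        """Number of FSFs per annotated minor category."""
        sizes = {m: 0 for m in self.minor_order}
        for minor in self.fsf_to_minor.values():
            if minor != NONA:
                sizes[minor] += 1
        return sizes

    def general_sizes(self) -> dict[str, int]:
        """Number of FSFs per general category."""
        sizes = {g: 0 for g in self.general_categories}
        for minor, n in self.minor_sizes().items():
            sizes[self.minor_to_general[minor]] += n
        return sizes

    def fsfs_of_minor(self, minor: str) -> tuple[str, ...]:
        return tuple(k for k, m in self.fsf_to_minor.items() if m == minor)


def _build_scheme(rows: Iterable[tuple[str, str, str]]) -> AnnotationScheme:
    """Assemble and validate a scheme from (fsf_key, minor, general) rows."""
    minor_to_general: dict[str, str] = {}
    fsf_to_minor: dict[str, str] = {}
    minor_order: list[str] = []
    canon_minor: dict[str, str] = {}
    for fsf_key, minor_raw, general_raw in rows:
        minor_is_nona = _norm(minor_raw) == _norm(NONA)
        minor = NONA if minor_is_nona else canon_minor.setdefault(
            _norm(minor_raw), " ".join(minor_raw.split())
        )
        if fsf_key.strip():
            key = parse_css(fsf_key).fsf_key
            if key in fsf_to_minor and fsf_to_minor[key] != minor:
                raise ValidationError(
                    f"FSF {key!r} listed under two minor categories: "
                    f"{fsf_to_minor[key]!r} and {minor!r}"
                )
            fsf_to_minor[key] = minor
        if minor_is_nona:
            continue
        general = canonical_general(general_raw)
        if minor in minor_to_general and minor_to_general[minor] != general:
            raise ValidationError(
                f"minor category {minor!r} listed under two general categories: "
                f"{minor_to_general[minor]!r} and {general!r}"
            )
        if minor not in minor_to_general:
            minor_to_general[minor] = general
            minor_order.append(minor)
    if not minor_to_general:
        raise ValidationError("annotation scheme contains no annotated FSFs")
    return AnnotationScheme(minor_to_general, fsf_to_minor, tuple(minor_order))


def read_annotation_scheme(path: str | Path) -> AnnotationScheme:
    """Read an FSF→(minor, general) scheme from a 3-column TSV."""
    df = _read_tsv(path, required=("fsf_key", "minor_category", "general_category"))
    if df.empty:
        raise ValidationError(f"empty annotation scheme: {path}")
    return _build_scheme(
        (r.fsf_key, r.minor_category, r.general_category)
        for r in df.itertuples(index=False)
    )


# -- packaged default scheme (published SCOP 1.73 category sizes) ----------

# Placeholder SCOP class letter per general category, used to mint
# deterministic synthetic FSF keys when expanding the packaged count table.
_PLACEHOLDER_CLASS = {
    "Metabolism": "a",
    "General": "b",
    "Information": "c",
    "Other": "d",
    "Extracellular processes": "e",
    "Intracellular processes": "f",
    "Regulation": "g",
    NONA: "k",
}


def load_minor_count_table() -> pd.DataFrame:
    """The packaged minor-category FSF count table (incl. the NONA row)."""
    with resources.files("fsfcensus").joinpath(
        "data/scop173_minor_counts.tsv"
    ).open("r") as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return df


def default_scheme() -> AnnotationScheme:
    """The packaged annotation scheme with synthetic placeholder FSF keys.

    Each minor category with n FSFs is expanded into keys
    ``<class>.<minor_index>.<1..n>`` where the class letter encodes the
    general category. Keys are synthetic placeholders — the published scheme
    does not enumerate FSF identities — but every category size is exact.
    """
    counts = load_minor_count_table()
    minor_to_general: dict[str, str] = {}
    fsf_to_minor: dict[str, str] = {}
    order: list[str] = []
    fold_by_class: dict[str, int] = {}
    for rec in counts.itertuples(index=False):
        is_nona = rec.general_category == NONA
        general = NONA if is_nona else canonical_general(rec.general_category)
        minor = " ".join(rec.minor_category.split())
        cls = _PLACEHOLDER_CLASS[general]
        fold = fold_by_class.get(cls, 0) + 1
        fold_by_class[cls] = fold
        for i in range(int(rec.n_fsf)):
            fsf_to_minor[f"{cls}.{fold}.{i + 1}"] = NONA if is_nona else minor
        if not is_nona:
            # empty minors (e.g. Storage) stay in the scheme vocabulary
            minor_to_general[minor] = general
            order.append(minor)
    return AnnotationScheme(minor_to_general, fsf_to_minor, tuple(order))


def write_annotation_scheme(scheme: AnnotationScheme, path: str | Path) -> None:
    """Write a scheme as the 3-column annotation TSV dialect.

    Minor categories with no FSFs are preserved as vocabulary rows with an
    empty ``fsf_key``, so write→read round-trips the full category set.
    """
    rows = [
        {
            "fsf_key": key,
            "minor_category": minor,
            "general_category": scheme.minor_to_general.get(minor, NONA),
        }
        for key, minor in scheme.fsf_to_minor.items()
    ]
    populated = set(scheme.fsf_to_minor.values())
    rows += [
        {
            "fsf_key": "",
            "minor_category": minor,
            "general_category": scheme.minor_to_general[minor],
        }
        for minor in scheme.minor_categories
        if minor not in populated
    ]
    pd.DataFrame(rows, columns=["fsf_key", "minor_category", "general_category"]).to_csv(
        path, sep="\t", index=False
    )


# --------------------------------------------------------------------------
# Assignment and genome tables
# --------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file has no header row") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {', '.join(missing)}")
    return df


_REGION_RE = re.compile(r"^\d+-\d+(,\d+-\d+)*$")


def parse_region(text: str) -> tuple[tuple[int, int], ...]:
    """Parse ``"1-100,150-220"`` into 1-based inclusive (start, end) pairs."""
    text = text.strip()
    if not _REGION_RE.fullmatch(text):
        raise FormatError(f"malformed region string {text!r}")
    pairs = []
    for chunk in text.split(","):
        start, end = (int(x) for x in chunk.split("-"))
        if start > end:
            raise FormatError(f"region start {start} > end {end} in {text!r}")
        pairs.append((start, end))
    return tuple(pairs)


class AssignmentTable(NamedTuple):
    """Parsed assignment rows plus the number of malformed rows skipped."""

    records: list[AssignmentRecord]
    skipped: int


def read_assignments(path: str | Path, strict: bool = True) -> AssignmentTable:
    """Read a domain-assignment TSV.

    In strict mode (default) any malformed row raises :class:`FormatError`;
    in lenient mode malformed rows are skipped, logged, and counted in the
    returned ``skipped`` field. Row order is preserved.
    """
    df = _read_tsv(path, required=("genome_id", "protein_id", "css", "region", "evalue"))
    records: list[AssignmentRecord] = []
    skipped = 0
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            evalue = float(row.evalue)
            if evalue != evalue:  # NaN
                raise ValueError("evalue is NaN")
            records.append(
                AssignmentRecord(
                    genome_id=str(row.genome_id),
                    protein_id=str(row.protein_id),
                    css=parse_css(row.css),
                    region=parse_region(row.region),
                    evalue=evalue,
                )
            )
        except (ValueError, FsfCensusError) as exc:
            if strict:
                raise FormatError(f"{path}: row {idx + 1}: {exc}") from exc
            skipped += 1
            logger.warning("%s: skipping malformed row %d: %s", path, idx + 1, exc)
    if skipped:
        logger.info("%s: skipped %d malformed row(s)", path, skipped)
    return AssignmentTable(records, skipped)


def write_assignments(records: Iterable[AssignmentRecord], path: str | Path) -> None:
    rows = [
        {
            "genome_id": r.genome_id,
            "protein_id": r.protein_id,
            "css": r.css.render(),
            "region": ",".join(f"{s}-{e}" for s, e in r.region),
            "evalue": f"{r.evalue:.3g}",
        }
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["genome_id", "protein_id", "css", "region", "evalue"]
    ).to_csv(path, sep="\t", index=False)


def read_genome_table(path: str | Path) -> list[GenomeRecord]:
    """Read per-genome metadata, validating closed-set fields and uniqueness."""
    df = _read_tsv(path, required=("genome_id", "superkingdom", "group", "lifestyle"))
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False)):
        gid = str(row.genome_id)
        if gid in seen:
            raise ValidationError(f"{path}: row {idx + 1}: duplicate genome_id {gid!r}")
        seen.add(gid)
        try:
            records.append(
                GenomeRecord(gid, str(row.superkingdom), str(row.group), str(row.lifestyle))
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {idx + 1}: {exc}") from None
    return records


def write_genome_table(genomes: Iterable[GenomeRecord], path: str | Path) -> None:
    rows = [
        {
            "genome_id": g.genome_id,
            "superkingdom": g.superkingdom,
            "group": g.group,
            "lifestyle": g.lifestyle,
        }
        for g in genomes
    ]
    pd.DataFrame(
        rows, columns=["genome_id", "superkingdom", "group", "lifestyle"]
    ).to_csv(path, sep="\t", index=False)
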