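"""Functional profiles: category counts and percentages per genome and pool.

Each genome's census row is pushed through the two-tier annotation scheme to
give counts of distinct FSFs per minor and general functional category.
Percentages use the genome's *annotated* repertoire as denominator — FSFs
with the reserved NONA label are excluded before any counting, so the seven
general-category percentages of a non-empty proteome sum to 100.

Pool summaries apply union semantics: an FSF present in any genome of the
pooled set contributes exactly once to its (single) category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .census import CensusMatrix
from .io import (
    NONA,
    AnnotationScheme,
    FormatError,
    GenomeRecord,
    ValidationError,
    _read_tsv,
)


def round2(x: float) -> float:
    """Round half-up to 2 decimals (banker's rounding would bias reports)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FunctionalProfile:
    """Per-genome counts and percentages over functional categories."""

    genome_id: str
    general_counts: dict[str, int]
    minor_counts: dict[str, int]
    total_annotated: int
    general_percent: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.general_counts.values()) != self.total_annotated:
            raise ValidationError(
                f"{self.genome_id}: general counts do not sum to total_annotated"
            )
        if sum(self.minor_counts.values()) != self.total_annotated:
            raise ValidationError(
                f"{self.genome_id}: minor counts do not sum to total_annotated"
            )
        if not self.general_percent:
            object.__setattr__(self, "general_percent", self._percents())

    def _percents(self) -> dict[str, float]:
        if self.total_annotated == 0:
            return {g: 0.0 for g in self.general_counts}
        return {
            g: 100.0 * n / self.total_annotated for g, n in self.general_counts.items()
        }

    def minor_percent(self) -> dict[str, float]:
        if self.total_annotated == 0:
            return {m: 0.0 for m in self.minor_counts}
        return {
            m: 100.0 * n / self.total_annotated for m, n in self.minor_counts.items()
        }


@dataclass(frozen=True)
class PoolSummary:
    """Distinct-FSF counts per category across a pooled set of genomes."""

    general_counts: dict[str, int]
    minor_counts: dict[str, int]
    pool_total: int

    def __post_init__(self) -> None:
        if sum(self.general_counts.values()) != self.pool_total:
            raise ValidationError("pool general counts do not sum to pool_total")

    def general_percent(self) -> dict[str, float]:
        if self.pool_total == 0:
            return {g: 0.0 for g in self.general_counts}
        return {g: 100.0 * n / self.pool_total for g, n in self.general_counts.items()}

    def minor_percent(self) -> dict[str, float]:
        if self.pool_total == 0:
            return {m: 0.0 for m in self.minor_counts}
        return {m: 100.0 * n / self.pool_total for m, n in self.minor_counts.items()}

    def ordering(self) -> list[str]:
        """General categories sorted by descending count, ties alphabetical."""
        return sorted(self.general_counts, key=lambda g: (-self.general_counts[g], g))


def _count_categories(
    fsf_keys: Iterable[str], scheme: AnnotationScheme
) -> tuple[dict[str, int], dict[str, int], int]:
    """Count annotated FSFs per (general, minor) category; NONA excluded."""
    general = {g: 0 for g in scheme.general_categories}
    minor = {m: 0 for m in scheme.minor_categories}
    total = 0
    for key in fsf_keys:
        m = scheme.minor_of(key)
        if m == NONA:
            continue
        minor[m] += 1
        general[scheme.minor_to_general[m]] += 1
        total += 1
    return general, minor, total


def profile_genome(
    matrix: CensusMatrix, genome_id: str, scheme: AnnotationScheme
) -> FunctionalProfile:
    """Functional profile of one genome from its census row."""
    if genome_id not in matrix.presence.index:
        raise ValidationError(f"unknown genome id {genome_id!r}")
    general, minor, total = _count_categories(matrix.fsfs_of(genome_id), scheme)
    return FunctionalProfile(genome_id, general, minor, total)


def profile_all(matrix: CensusMatrix, scheme: AnnotationScheme) -> list[FunctionalProfile]:
    return [profile_genome(matrix, g, scheme) for g in matrix.genome_ids]


def pool_summary(
    matrix: CensusMatrix,
    genome_subset: Sequence[str] | None,
    scheme: AnnotationScheme,
) -> PoolSummary:
    """Pooled category counts over a genome subset (None = all genomes)."""
    subset = list(matrix.genome_ids) if genome_subset is None else list(genome_subset)
    if not subset:
        raise ValidationError("pool_summary requires a non-empty genome subset")
    missing = [g for g in subset if g not in matrix.presence.index]
    if missing:
        raise ValidationError(f"genome(s) not in census: {', '.join(missing)}")
    sub = matrix.presence.loc[subset]
    pooled = sub.columns[(sub.to_numpy() == 1).any(axis=0)]
    general, minor, total = _count_categories(pooled, scheme)
    return PoolSummary(general, minor, total)


def scheme_pool(scheme: AnnotationScheme) -> PoolSummary:
    """Pool summary of the annotation scheme itself (every annotated FSF)."""
    general, minor, total = _count_categories(scheme.fsf_to_minor, scheme)
    return PoolSummary(general, minor, total)


@dataclass(frozen=True)
class GroupMeans:
    """Unweighted per-genome means of counts and percentages for one label."""

    label: str
    n_genomes: int
    mean_general_counts: dict[str, float]
    mean_general_percent: dict[str, float]
    mean_minor_counts: dict[str, float]
    mean_total_annotated: float


def group_profiles(
    profiles: Sequence[FunctionalProfile],
    genomes: Sequence[GenomeRecord],
    key: str,
) -> dict[str, GroupMeans]:
    """Average profiles within superkingdom / group / lifestyle labels.

    Means are unweighted across genomes (each proteome contributes equally,
    matching per-proteome trend plots, not FSF-weighted pooling).
    """
    if key not in ("superkingdom", "group", "lifestyle"):
        raise ValidationError(f"unknown grouping key {key!r}")
    meta = {g.genome_id: getattr(g, key) for g in genomes}
    missing = [p.genome_id for p in profiles if p.genome_id not in meta]
    if missing:
        raise ValidationError(
            f"profile(s) without metadata row: {', '.join(missing[:5])}"
        )
    by_label: dict[str, list[FunctionalProfile]] = {}
    for p in profiles:
        by_label.setdefault(meta[p.genome_id], []).append(p)

    def _mean(dicts: list[Mapping[str, float]]) -> dict[str, float]:
        keys = dicts[0].keys()
        return {k: sum(d[k] for d in dicts) / len(dicts) for k in keys}

    out: dict[str, GroupMeans] = {}
    for label in sorted(by_label):
        members = by_label[label]
        out[label] = GroupMeans(
            label=label,
            n_genomes=len(members),
            mean_general_counts=_mean([m.general_counts for m in members]),
            mean_general_percent=_mean([m.general_percent for m in members]),
            mean_minor_counts=_mean([m.minor_counts for m in members]),
            mean_total_annotated=sum(m.total_annotated for m in members)
            / len(members),
        )
    return out


# --------------------------------------------------------------------------
# Profile TSV round-trip
# --------------------------------------------------------------------------


def _profile_columns(scheme_generals: Sequence[str], minors: Sequence[str]) -> list[str]:
    cols = ["genome_id", "total_annotated"]
    for g in scheme_generals:
        cols += [f"count::{g}", f"pct::{g}"]
    cols += [f"count::{m}" for m in minors]
    return cols


def write_profiles(
    profiles: Sequence[FunctionalProfile], path: str | Path
) -> None:
    """Write profiles as TSV with a stable published-table column order.

    Percentages are reported rounded half-up to 2 decimals; counts are
    written exactly and round-trip through :func:`read_profiles`.
    """
    if profiles:
        generals = list(profiles[0].general_counts)
        minors = list(profiles[0].minor_counts)
        for p in profiles[1:]:
            if list(p.general_counts) != generals or list(p.minor_counts) != minors:
                raise ValidationError(
                    "profiles with heterogeneous category sets cannot share a table"
                )
    else:
        generals, minors = [], []
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "genome_id": p.genome_id,
            "total_annotated": p.total_annotated,
        }
        for g in generals:
            row[f"count::{g}"] = p.general_counts[g]
            row[f"pct::{g}"] = round2(p.general_percent[g])
        for m in minors:
            row[f"count::{m}"] = p.minor_counts[m]
        rows.append(row)
    pd.DataFrame(rows, columns=_profile_columns(generals, minors)).to_csv(
        path, sep="\t", index=False
    )


def read_profiles(path: str | Path, scheme: AnnotationScheme) -> list[FunctionalProfile]:
    """Read back a profiles TSV; percentages are recomputed from counts."""
    df = _read_tsv(path, required=("genome_id", "total_annotated"))
    generals = list(scheme.general_categories)
    minors = list(scheme.minor_categories)
    for col in [f"count::{g}" for g in generals] + [f"count::{m}" for m in minors]:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    out = []
    # plain tuples: '::' column names are not valid identifiers
    for row in df.itertuples(index=False, name=None):
        vals = dict(zip(df.columns, row))
        out.append(
            FunctionalProfile(
                genome_id=str(vals["genome_id"]),
                general_counts={g: int(vals[f"count::{g}"]) for g in generals},
                minor_counts={m: int(vals[f"count::{m}"]) for m in minors},
                total_annotated=int(vals["total_annotated"]),
            )
        )
    return out
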