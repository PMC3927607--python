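"""Robust-deviation screen for proteomes that break their group's signature.

Reduced (parasitic/symbiotic) proteomes stand out from the otherwise highly
conserved functional make-up of their superkingdom — typically trading
Metabolism for Information FSFs. The screen formalizes that call: within
each reference group (superkingdom by default) and each general category it
computes a robust z-score,

    z = (x - median) / (1.4826 * MAD),

on per-genome category percentages (or counts), and flags |z| >= threshold
(default 3.5, the conventional cutoff for the MAD rule). The median/MAD
pair keeps the screen insensitive to the very outliers it hunts, unlike a
mean/SD z-score which parasite-heavy tails would mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import median_abs_deviation

from .io import GenomeRecord, ValidationError
from .profiles import FunctionalProfile

#: Minimum group size for a meaningful median/MAD estimate.
MIN_GROUP_SIZE = 5

DEFAULT_THRESHOLD = 3.5


@dataclass(frozen=True)
class OutlierFlag:
    """Robust z of one genome in one category against its reference group."""

    genome_id: str
    category: str
    robust_z: float
    flagged: bool
    reference_group: str


def detect_outliers(
    profiles: Sequence[FunctionalProfile],
    genomes: Sequence[GenomeRecord],
    key: str = "superkingdom",
    threshold: float = DEFAULT_THRESHOLD,
    mode: str = "percent",
) -> list[OutlierFlag]:
    """MAD-based robust z screen of category percentages within groups.

    ``mode`` selects the screened quantity: ``"percent"`` (category share of
    the annotated repertoire, the published-figure scale where outliers were
    marked) or ``"count"`` (raw category counts). Groups with fewer than
    ``MIN_GROUP_SIZE`` members are skipped with a warning; categories whose
    group MAD is zero are skipped (a constant column supports no deviation
    measure). Output is ordered by (genome_id, category).
    """
    if threshold <= 0:
        raise ValidationError(f"threshold must be positive, got {threshold}")
    if mode not in ("percent", "count"):
        raise ValidationError(f"mode must be 'percent' or 'count', got {mode!r}")
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

    flags: list[OutlierFlag] = []
    for label in sorted(by_label):
        members = by_label[label]
        if len(members) < MIN_GROUP_SIZE:
            warnings.warn(
                f"group {label!r} has only {len(members)} member(s); "
                f"skipped (need >= {MIN_GROUP_SIZE})",
                stacklevel=2,
            )
            continue
        categories = list(members[0].general_counts)
        for category in categories:
            if mode == "percent":
                values = np.array([m.general_percent[category] for m in members])
            else:
                values = np.array(
                    [float(m.general_counts[category]) for m in members]
                )
            med = float(np.median(values))
            scaled_mad = float(median_abs_deviation(values, scale="normal"))
            if scaled_mad == 0.0:
                warnings.warn(
                    f"group {label!r}, category {category!r}: MAD is zero; "
                    "category skipped",
                    stacklevel=2,
                )
                continue
            z = (values - med) / scaled_mad
            for member, zi in zip(members, z):
                flags.append(
                    OutlierFlag(
                        genome_id=member.genome_id,
                        category=category,
                        robust_z=float(zi),
                        flagged=bool(abs(zi) >= threshold),
                        reference_group=label,
                    )
                )
    flags.sort(key=lambda f: (f.genome_id, f.category))
    return flags


def flagged_genomes(flags: Sequence[OutlierFlag]) -> list[str]:
    """Genomes flagged in at least one category, sorted."""
    return sorted({f.genome_id for f in flags if f.flagged})
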