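"""Presence/absence census of fold superfamilies (FSFs) per genome.

Domain assignments are filtered at an E-value cutoff (default 1e-4, the
stringent threshold conventionally used to suppress false-positive HMM
hits), collapsed from fold-family to FSF resolution, and reduced to the set
of unique FSFs per proteome. Copy numbers are deliberately discarded: the
census is strictly binary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AnnotationScheme, AssignmentRecord, GenomeRecord, NONA, ValidationError


@dataclass(frozen=True)
class CensusConfig:
    """E-value filtering policy. ``inclusive`` keeps hits with E <= cutoff."""

    evalue_cutoff: float = 1e-4
    inclusive: bool = True

    def __post_init__(self) -> None:
        if not self.evalue_cutoff > 0:
            raise ValidationError(f"evalue_cutoff must be > 0, got {self.evalue_cutoff}")

    def keeps(self, evalue: float) -> bool:
        if self.inclusive:
            return evalue <= self.evalue_cutoff
        return evalue < self.evalue_cutoff


@dataclass(frozen=True)
class CensusMatrix:
    """Genomes x FSFs binary presence matrix.

    ``presence`` is a pandas DataFrame with genome ids as index (input
    metadata order), lexicographically sorted FSF keys as columns, and
    uint8 0/1 entries.
    """

    presence: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.presence.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValidationError("census entries must be 0 or 1")
        if self.presence.index.has_duplicates:
            raise ValidationError("duplicate genome ids in census")
        if self.presence.columns.has_duplicates:
            raise ValidationError("duplicate FSF keys in census")

    @property
    def genome_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def fsf_keys(self) -> list[str]:
        return list(self.presence.columns)

    def repertoire_size(self, genome_id: str) -> int:
        """Number of distinct FSFs present in one proteome."""
        return int(self.presence.loc[genome_id].sum())

    def fsfs_of(self, genome_id: str) -> list[str]:
        row = self.presence.loc[genome_id]
        return list(row.index[row == 1])


def filter_by_evalue(
    records: Sequence[AssignmentRecord], config: CensusConfig | None = None
) -> list[AssignmentRecord]:
    """Keep assignments passing the E-value cutoff; order preserved."""
    config = config or CensusConfig()
    return [r for r in records if config.keeps(r.evalue)]


def build_census(
    records: Sequence[AssignmentRecord], genomes: Sequence[GenomeRecord]
) -> CensusMatrix:
    """Collapse assignments to the per-genome set of unique FSFs.

    Every record's genome must appear in ``genomes``; genomes with no
    records get all-zero rows. FF-level css collapse to their FSF key.
    """
    genome_ids = [g.genome_id for g in genomes]
    if len(set(genome_ids)) != len(genome_ids):
        raise ValidationError("duplicate genome ids in metadata")
    known = set(genome_ids)
    orphans = sorted({r.genome_id for r in records} - known)
    if orphans:
        raise ValidationError(
            f"assignment records for genome(s) absent from metadata: {', '.join(orphans)}"
        )
    pairs = pd.DataFrame(
        {
            "genome_id": [r.genome_id for r in records],
            "fsf_key": [r.fsf_key for r in records],
        }
    )
    fsf_keys = sorted(pairs["fsf_key"].unique()) if len(pairs) else []
    presence = pd.DataFrame(
        0, index=pd.Index(genome_ids, name="genome_id"), columns=fsf_keys, dtype=np.uint8
    )
    if len(pairs):
        uniq = pairs.drop_duplicates()
        presence.values[
            presence.index.get_indexer(uniq["genome_id"]),
            presence.columns.get_indexer(uniq["fsf_key"]),
        ] = 1
    return CensusMatrix(presence)


def partition_annotated(
    matrix: CensusMatrix, scheme: AnnotationScheme
) -> tuple[list[str], list[str]]:
    """Split census FSF keys into (annotated, NONA) per the scheme.

    Keys absent from the scheme are treated as NONA (annotation files and
    assignment tables routinely come from slightly different SCOP versions).
    """
    annotated = [k for k in matrix.fsf_keys if scheme.minor_of(k) != NONA]
    nona = [k for k in matrix.fsf_keys if scheme.minor_of(k) == NONA]
    return annotated, nona
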