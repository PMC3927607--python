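"""Synthetic proteome cohorts with the census structure of real datasets.

The generator emulates the statistical shape of a comparative FSF census:

* per-superkingdom total repertoire sizes ordered Archaea < Bacteria <
  Eukarya, drawn uniformly from configurable ranges;
* per-genome category composition drawn from a Dirichlet around a
  superkingdom base profile (Metabolism dominant everywhere; prokaryotes
  relatively elevated in Information, Eukarya in Regulation/ICP/ECP), so
  profiles are conserved-but-overdispersed the way per-proteome trend
  lines are;
* FSF identity sampling within each category from the packaged annotation
  scheme (minor-category splits follow the hypergeometric induced by the
  scheme's minor sizes);
* expansion of each present FSF into fold-family-level assignment rows
  with E-values below the census cutoff, plus decoy rows above the cutoff
  drawn from FSFs absent from the genome;
* planted "reductively evolved parasite" outliers among P/OP genomes:
  repertoire shrunk by a size factor and a Metabolism->Information
  probability-mass shift (the two deltas sum to zero by construction).

Everything is driven by one ``numpy.random.Generator``; the same seed
reproduces byte-identical output files. Ground truth (realized category
counts and planted-outlier labels) is written to ``truth.json`` so that
downstream recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    GENERAL_CATEGORIES,
    AnnotationScheme,
    GenomeRecord,
    ValidationError,
    default_scheme,
    write_annotation_scheme,
    write_genome_table,
)
from .profiles import FunctionalProfile

# Default cohort composition: genomes per (superkingdom, lifestyle) cell,
# mirroring a 965-proteome census (70 A / 651 B / 244 E; 592 FL, 153 P,
# 158 OP; the archaeal parasite cell is nearly empty, as observed).
DEFAULT_N_GENOMES: dict[tuple[str, str], int] = {
    ("Archaea", "FL"): 68,
    ("Archaea", "OP"): 2,
    ("Bacteria", "FL"): 380,
    ("Bacteria", "P"): 130,
    ("Bacteria", "OP"): 141,
    ("Eukarya", "FL"): 144,
    ("Eukarya", "P"): 23,
    ("Eukarya", "OP"): 15,
}

# Total annotated-repertoire ranges (distinct FSFs per proteome). Chosen so
# Metabolism at ~1/3 of content lands near published metabolic-repertoire
# ranges and per-category mean counts increase Archaea < Bacteria < Eukarya.
DEFAULT_REPERTOIRE_RANGE: dict[str, tuple[int, int]] = {
    "Archaea": (420, 520),
    "Bacteria": (500, 700),
    "Eukarya": (700, 900),
}

# Base 7-category proportions per superkingdom, in GENERAL_CATEGORIES order
# (Metabolism, General, Information, Other, ECP, ICP, Regulation). Generator
# parameters set from qualitative trend descriptions, not measured values.
DEFAULT_PROPORTIONS: dict[str, tuple[float, ...]] = {
    "Archaea": (0.35, 0.07, 0.19, 0.10, 0.04, 0.12, 0.13),
    "Bacteria": (0.36, 0.07, 0.17, 0.11, 0.05, 0.13, 0.11),
    "Eukarya": (0.28, 0.09, 0.15, 0.12, 0.06, 0.15, 0.15),
}

_GROUP_LABELS: dict[str, tuple[str, ...]] = {
    "Archaea": ("Euryarchaeota", "Crenarchaeota", "Thaumarchaeota"),
    "Bacteria": ("Proteobacteria", "Firmicutes", "Actinobacteria", "Tenericutes"),
    "Eukarya": ("Metazoa", "Fungi", "Plants", "Protista"),
}


@dataclass(frozen=True)
class OutlierSpec:
    """Planted reductive-evolution signature for designated P/OP genomes.

    ``fraction`` of P/OP genomes get ``metabolism_delta`` added to their
    Metabolism base proportion and ``information_delta`` to Information
    (the deltas must cancel), and their repertoire size is multiplied by
    ``size_factor`` — reduced proteomes that trade metabolic for
    informational FSFs.
    """

    fraction: float = 0.25
    metabolism_delta: float = -0.15
    information_delta: float = 0.15
    size_factor: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValidationError("outlier fraction must be in [0, 1]")
        if abs(self.metabolism_delta + self.information_delta) > 1e-12:
            raise ValidationError(
                "metabolism_delta and information_delta must sum to zero"
            )
        if not 0.0 < self.size_factor <= 1.0:
            raise ValidationError("size_factor must be in (0, 1]")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of one synthetic cohort."""

    seed: int = 0
    n_genomes: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_N_GENOMES)
    )
    repertoire_size_range: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_REPERTOIRE_RANGE)
    )
    category_proportions: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    dirichlet_concentration: float = 200.0
    outlier_spec: OutlierSpec = field(default_factory=OutlierSpec)
    evalue_noise: float = 0.2
    ff_multiplicity: float = 2.0
    evalue_cutoff: float = 1e-4

    def __post_init__(self) -> None:
        for sk, props in self.category_proportions.items():
            arr = np.asarray(props, dtype=float)
            if arr.shape != (len(GENERAL_CATEGORIES),):
                raise ValidationError(
                    f"{sk}: need {len(GENERAL_CATEGORIES)} category proportions"
                )
            if (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-9:
                raise ValidationError(f"{sk}: proportions must be a simplex vector")
        for sk, (lo, hi) in self.repertoire_size_range.items():
            if not (0 < lo <= hi):
                raise ValidationError(f"{sk}: invalid repertoire range ({lo}, {hi})")
        if self.dirichlet_concentration <= 0:
            raise ValidationError("dirichlet_concentration must be positive")
        if not 0.0 <= self.evalue_noise < 1.0:
            raise ValidationError("evalue_noise must be in [0, 1)")
        if self.ff_multiplicity < 1.0:
            raise ValidationError("ff_multiplicity must be >= 1")
        for (sk, lifestyle), n in self.n_genomes.items():
            if sk not in self.repertoire_size_range:
                raise ValidationError(f"no repertoire range for superkingdom {sk!r}")
            if n < 0:
                raise ValidationError(f"negative genome count for ({sk}, {lifestyle})")


@dataclass(frozen=True)
class Cohort:
    """Ground truth of one generated cohort, before any file I/O."""

    genomes: list[GenomeRecord]
    general_counts: pd.DataFrame  # genomes x 7 general categories
    minor_counts: pd.DataFrame  # genomes x annotated minor categories
    outlier_ids: frozenset[str]

    def truth_profiles(self) -> list[FunctionalProfile]:
        """FunctionalProfile objects built directly from the truth counts."""
        out = []
        for g in self.genomes:
            gen = {
                c: int(self.general_counts.at[g.genome_id, c])
                for c in self.general_counts.columns
            }
            mino = {
                m: int(self.minor_counts.at[g.genome_id, m])
                for m in self.minor_counts.columns
            }
            out.append(FunctionalProfile(g.genome_id, gen, mino, sum(gen.values())))
        return out


def _check_quota_feasibility(config: SyntheticConfig, scheme: AnnotationScheme) -> None:
    """A category whose expected demand can exceed its FSF pool is a config error."""
    sizes = scheme.general_sizes()
    spec = config.outlier_spec
    deltas = np.zeros(len(GENERAL_CATEGORIES))
    deltas[GENERAL_CATEGORIES.index("Metabolism")] = spec.metabolism_delta
    deltas[GENERAL_CATEGORIES.index("Information")] = spec.information_delta
    for (sk, lifestyle), n in config.n_genomes.items():
        if n == 0:
            continue
        lo, hi = config.repertoire_size_range[sk]
        base = np.asarray(config.category_proportions[sk], dtype=float)
        variants = [(base, hi)]
        if lifestyle in ("P", "OP") and spec.fraction > 0:
            variants.append(
                (base + deltas, int(round(hi * spec.size_factor)))
            )
        for props, n_fsf in variants:
            if (props < 0).any():
                raise ValidationError(
                    f"{sk}/{lifestyle}: outlier deltas drive a proportion negative"
                )
            for cat, p in zip(GENERAL_CATEGORIES, props):
                demand = p * n_fsf
                if demand > sizes.get(cat, 0):
                    raise ValidationError(
                        f"{sk}/{lifestyle}: expected quota {demand:.0f} for "
                        f"category {cat!r} exceeds the scheme's {sizes.get(cat, 0)} FSFs"
                    )


def _cap_redistribute(counts: np.ndarray, caps: np.ndarray) -> np.ndarray:
    """Clip counts at category capacity, moving excess to spare capacity.

    Deterministic: excess is poured into the categories with the most
    headroom first. Overflow is a rare tail event under default settings.
    """
    counts = counts.copy()
    excess = int(np.maximum(counts - caps, 0).sum())
    counts = np.minimum(counts, caps)
    while excess > 0:
        headroom = caps - counts
        order = np.argsort(-headroom)
        target = order[0]
        if headroom[target] <= 0:
            raise ValidationError("repertoire size exceeds total scheme capacity")
        take = min(excess, int(headroom[target]))
        counts[target] += take
        excess -= take
    return counts


def generate_truth(
    config: SyntheticConfig, scheme: AnnotationScheme | None = None
) -> Cohort:
    """Sample genome metadata and true per-category FSF counts.

    This is the count-level core of the generator: repertoire size,
    Dirichlet-multinomial general-category allocation (clipped at each
    category's FSF pool), and hypergeometric minor-category splits. FSF
    identities and assignment rows are layered on top by
    :func:`generate_cohort`.
    """
    scheme = scheme or default_scheme()
    _check_quota_feasibility(config, scheme)
    rng = np.random.default_rng(config.seed)
    general_sizes = scheme.general_sizes()
    caps = np.array([general_sizes.get(c, 0) for c in GENERAL_CATEGORIES])
    minor_sizes = scheme.minor_sizes()
    minors_by_general: dict[str, list[str]] = {c: [] for c in GENERAL_CATEGORIES}
    for m in scheme.minor_categories:
        minors_by_general[scheme.minor_to_general[m]].append(m)

    spec = config.outlier_spec
    m_idx = GENERAL_CATEGORIES.index("Metabolism")
    i_idx = GENERAL_CATEGORIES.index("Information")

    genomes: list[GenomeRecord] = []
    general_rows: list[np.ndarray] = []
    minor_rows: list[dict[str, int]] = []
    outlier_ids: set[str] = set()

    cells = sorted(config.n_genomes.items())
    counter = 0
    for (sk, lifestyle), n in cells:
        lo, hi = config.repertoire_size_range[sk]
        base = np.asarray(config.category_proportions[sk], dtype=float)
        n_outliers = (
            int(round(n * spec.fraction)) if lifestyle in ("P", "OP") else 0
        )
        for j in range(n):
            counter += 1
            gid = f"{sk[:3].lower()}_{lifestyle.lower()}_{counter:04d}"
            group = str(rng.choice(_GROUP_LABELS[sk]))
            is_outlier = j < n_outliers
            size = int(rng.integers(lo, hi + 1))
            props = base.copy()
            if is_outlier:
                size = max(2, int(round(size * spec.size_factor)))
                props[m_idx] += spec.metabolism_delta
                props[i_idx] += spec.information_delta
                outlier_ids.add(gid)
            alpha = np.maximum(config.dirichlet_concentration * props, 1e-6)
            p_g = rng.dirichlet(alpha)
            counts = rng.multinomial(size, p_g)
            counts = _cap_redistribute(counts, caps)
            # minor split: the category's FSFs are drawn uniformly without
            # replacement, so minors follow a multivariate hypergeometric
            minor_row: dict[str, int] = {m: 0 for m in scheme.minor_categories}
            for cat, k in zip(GENERAL_CATEGORIES, counts):
                minors = minors_by_general[cat]
                if not minors or k == 0:
                    continue
                colors = np.array([minor_sizes[m] for m in minors])
                split = rng.multivariate_hypergeometric(colors, int(k))
                for m, q in zip(minors, split):
                    minor_row[m] = int(q)
            genomes.append(GenomeRecord(gid, sk, group, lifestyle))
            general_rows.append(counts)
            minor_rows.append(minor_row)

    gids = [g.genome_id for g in genomes]
    general_df = pd.DataFrame(
        general_rows, index=pd.Index(gids, name="genome_id"), columns=GENERAL_CATEGORIES
    )
    minor_df = pd.DataFrame(
        minor_rows, index=pd.Index(gids, name="genome_id")
    ).fillna(0).astype(int)
    minor_df = minor_df[[m for m in scheme.minor_categories]]
    return Cohort(genomes, general_df, minor_df, frozenset(outlier_ids))


def _assignment_rows(
    cohort: Cohort,
    scheme: AnnotationScheme,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Expand truth counts into FF-level assignment rows with decoys."""
    keys_by_minor = {m: sorted(scheme.fsfs_of_minor(m)) for m in scheme.minor_categories}
    all_keys = np.array(sorted(scheme.fsf_to_minor))
    rows: list[tuple[str, str, str, str, str]] = []
    log_cut = np.log10(config.evalue_cutoff)
    for g in cohort.genomes:
        gid = g.genome_id
        present: list[str] = []
        for m in scheme.minor_categories:
            q = int(cohort.minor_counts.at[gid, m])
            if q == 0:
                continue
            pool = keys_by_minor[m]
            idx = rng.choice(len(pool), size=q, replace=False)
            present.extend(pool[i] for i in idx)
        present_set = set(present)
        n_true = 0
        prot = 0
        for key in present:
            n_copies = 1 + int(rng.poisson(config.ff_multiplicity - 1.0))
            for _ in range(n_copies):
                prot += 1
                n_true += 1
                ff = int(rng.integers(1, 21))
                start = int(rng.integers(1, 500))
                length = int(rng.integers(50, 300))
                ev = 10.0 ** rng.uniform(-30.0, log_cut)
                rows.append(
                    (
                        gid,
                        f"{gid}_p{prot:05d}",
                        f"{key}.{ff}",
                        f"{start}-{start + length}",
                        f"{ev:.3e}",
                    )
                )
        if config.evalue_noise > 0 and n_true:
            n_decoy = int(round(config.evalue_noise * n_true / (1 - config.evalue_noise)))
            absent = all_keys[~np.isin(all_keys, list(present_set))]
            for _ in range(n_decoy):
                prot += 1
                key = str(absent[rng.integers(len(absent))]) if len(absent) else str(
                    all_keys[rng.integers(len(all_keys))]
                )
                ff = int(rng.integers(1, 21))
                start = int(rng.integers(1, 500))
                length = int(rng.integers(50, 300))
                # strictly above the cutoff: always rejected by the census
                ev = 10.0 ** rng.uniform(log_cut + 0.5, 1.0)
                rows.append(
                    (
                        gid,
                        f"{gid}_p{prot:05d}",
                        f"{key}.{ff}",
                        f"{start}-{start + length}",
                        f"{ev:.3e}",
                    )
                )
    return pd.DataFrame(
        rows, columns=["genome_id", "protein_id", "css", "region", "evalue"]
    )


def generate_cohort(
    config: SyntheticConfig,
    out_dir: str | Path,
    scheme: AnnotationScheme | None = None,
) -> Cohort:
    """Generate and write a full synthetic cohort.

    Writes ``assignments.tsv``, ``genomes.tsv``, ``annotation.tsv`` and
    ``truth.json`` into ``out_dir``. Fully deterministic given
    ``config.seed``; returns the in-memory :class:`Cohort` ground truth.
    """
    scheme = scheme or default_scheme()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_truth(config, scheme)
    # one generator stream for the expansion layer, offset from the truth
    # stream so truth counts are identical with and without expansion
    rng = np.random.default_rng((config.seed, 1))
    assignments = _assignment_rows(cohort, scheme, config, rng)
    assignments.to_csv(out / "assignments.tsv", sep="\t", index=False)
    write_genome_table(cohort.genomes, out / "genomes.tsv")
    write_annotation_scheme(scheme, out / "annotation.tsv")
    truth = {
        "seed": config.seed,
        "evalue_cutoff": config.evalue_cutoff,
        "outliers": sorted(cohort.outlier_ids),
        "genomes": {
            g.genome_id: {
                "superkingdom": g.superkingdom,
                "group": g.group,
                "lifestyle": g.lifestyle,
                "is_outlier": g.genome_id in cohort.outlier_ids,
                "total_annotated": int(
                    cohort.general_counts.loc[g.genome_id].sum()
                ),
                "general_counts": {
                    c: int(cohort.general_counts.at[g.genome_id, c])
                    for c in GENERAL_CATEGORIES
                },
                "minor_counts": {
                    m: int(cohort.minor_counts.at[g.genome_id, m])
                    for m in cohort.minor_counts.columns
                },
            }
            for g in cohort.genomes
        },
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return cohort
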