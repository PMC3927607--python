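# Methods

## The census model

`fsfcensus` treats a proteome as the *set of distinct SCOP fold
superfamilies (FSFs)* detectable in its protein complement. Domain
assignments arrive as tables of HMM hits, one row per assigned domain
region, each carrying a concise classification string (css) such as
`c.26.1.2` (class `c`, fold 26, FSF 1, fold family 2) and an E-value.
The pipeline:

1. filters hits at an E-value cutoff (default `1e-4`, inclusive — the
   stringent threshold conventionally used with SUPERFAMILY-style
   assignments to suppress false positives; thresholds are read as maxima,
   so `E == cutoff` is kept);
2. collapses fold-family-level css to their FSF key (first three tokens)
   and reduces each genome to its set of unique FSFs — a binary
   genomes × FSFs presence matrix. Copy number is deliberately discarded;
   every downstream quantity is about repertoire composition, not
   abundance;
3. maps FSFs through a two-tier functional annotation scheme
   (FSF → minor category → general category) and reports per-genome counts
   and percentages over the 7 general and 49 annotated minor categories.
   FSFs labelled `NONA` ("not annotated"), *including any FSF key absent
   from the scheme*, are excluded before counting, so percentages are
   shares of the genome's annotated repertoire and sum to 100. Treating
   unknown keys as NONA rather than errors tolerates routine SCOP version
   skew between assignment and annotation files.

Pooled summaries use union semantics: an FSF present in at least one
genome of a pooled set contributes exactly once, to its single category
(the scheme is a one-to-one mapping; multifunctional domains carry their
predominant function). Group summaries (superkingdom, phylum/kingdom,
lifestyle) are unweighted arithmetic means over genomes, matching
per-proteome trend curves rather than FSF-weighted pooling.

## The packaged annotation scheme

The package ships the published SCOP 1.73 SUPERFAMILY category-size table
(`data/scop173_minor_counts.tsv`): 7 general categories, 49 annotated
minor categories (three of them empty at this SCOP release: Storage,
Nuclear structure, Trafficking/secretion), 1,646 annotated FSFs, and 135
`NONA` FSFs (1,781 total). Counting `NONA` as the reserved 50th label
recovers the scheme's usual "7 general / 50 detailed" description. The
FSF identities behind those counts are not distributed with the scheme,
so `default_scheme()` expands the count table into deterministic
*synthetic placeholder keys* (`a.1.1`, `a.1.2`, …, class letter encoding
the general category). Every category size — and therefore every pooled
count, percentage and ordering computed from the scheme — is exact; only
the key strings are synthetic. A scheme with real keys drops in through
`read_annotation_scheme` (3-column TSV; rows with an empty `fsf_key`
declare an empty minor category).

Reported percentages are rounded half-up to two decimals in outputs
(`round2`) and kept at full precision internally.

## Statistics

**Normalization.** Per-category FSF counts are rescaled before testing:

```
N_normal = (log10(N_xy) / log10(N_max)) * 7
```

with `N_xy` the count of category *x* in proteome *y* and `N_max` the
largest entry of the full 7-category × proteome count matrix under
analysis (computed once per analysis, not per category). The transform
maps 1 → 0 and `N_max` → 7 and is strictly increasing; it requires
`N_xy ≥ 1` and `N_max ≥ 2`. Zero counts have no logarithm and are
excluded with a warning rather than pseudo-counted — no general-category
count of a real proteome is plausibly zero, so exclusion is transparent
and safe. A `normalize=False` switch runs the test on raw counts.

**Welch's ANOVA.** Cross-superkingdom comparisons use Welch's
unequal-variance ANOVA, implemented directly from the defining formulas
(precision weights `w_i = n_i/s_i²`, weighted grand mean, `Λ`-correction,
`F` with `(k−1, 1/(3Λ))` degrees of freedom); the p-value is the upper
F-tail via the regularized incomplete beta (`scipy.stats.f.sf`, accurate
to ~1e-12 here). Correctness is pinned by three independent oracles in the
test suite: the two-group identity `F = t²` against an independent Welch
t-test, a three-group cross-check against `pingouin.welch_anova`, and
simulated-null type-I error calibration. Groups need `n ≥ 2` and positive
variance; degenerate groups raise instead of silently propagating
infinities. Only free-living (FL) genomes enter superkingdom comparisons:
parasitic lifestyles carry reductively evolved repertoires whose inclusion
inflates within-group variance.

**Outlier screen.** The screen formalizes "which proteomes break their
group's signature" as a robust univariate rule: within each reference
group and general category, `z = (x − median)/(1.4826·MAD)` on category
percentages (counts mode available), flag `|z| ≥ 3.5`. Median/MAD keep
the estimate insensitive to the heavy lower tails that parasite-rich
groups produce; 3.5 is the conventional MAD-rule cutoff and is exposed as
a parameter. Groups smaller than 5 are skipped (no stable MAD), and a
zero-MAD category is skipped with a warning — a constant column supports
no deviation measure. A genome is called an outlier if flagged in at
least one category. The screen is univariate by design; no Mahalanobis
variant is attempted.

## The synthetic cohort generator

The generator produces cohorts whose *structure* matches a comparative
functional census; its parameters are generator settings, not measured
values. Defaults:

* **Cohort composition** mirrors a 965-proteome census: 70 Archaea
  (68 FL / 2 OP), 651 Bacteria (380 FL / 130 P / 141 OP), 244 Eukarya
  (144 FL / 23 P / 15 OP) — 592 FL, 153 P, 158 OP in total.
* **Repertoire sizes** (distinct annotated FSFs per proteome) are uniform
  on Archaea (420, 520), Bacteria (500, 700), Eukarya (700, 900). These
  are *total* repertoire ranges chosen so that Metabolism at roughly a
  third of content lands near reported metabolic-repertoire ranges and
  per-category mean counts increase Archaea < Bacteria < Eukarya — the
  ordering the method is meant to detect.
* **Composition**: per-genome category proportions are Dirichlet around a
  superkingdom base vector (concentration 200 — tight, conserved
  profiles; the concentration is a free parameter, since conservation is
  reported qualitatively, not as a variance). Base vectors (Metabolism,
  General, Information, Other, ECP, ICP, Regulation):
  Archaea (.35,.07,.19,.10,.04,.12,.13), Bacteria
  (.36,.07,.17,.11,.05,.13,.11), Eukarya (.28,.09,.15,.12,.06,.15,.15) —
  Metabolism dominant everywhere, prokaryotes relatively elevated in
  Information share, Eukarya in Regulation/ICP/ECP/General, and every
  category's *count* separated across superkingdoms, since the planted
  cross-superkingdom effect is the property the statistics module is
  tested against.
* **Category allocation** is multinomial given the Dirichlet draw,
  clipped at each category's FSF pool with deterministic redistribution
  of the (rare) overflow; minor categories split by multivariate
  hypergeometric, i.e. category members drawn uniformly without
  replacement. Realized (post-clip) counts are the ground truth written
  to `truth.json`.
* **Assignment expansion**: each present FSF becomes
  `1 + Poisson(ff_multiplicity − 1)` fold-family-level rows with
  log-uniform E-values below the cutoff; decoy rows (default 20% of the
  table) use FSFs absent from the genome with E-values strictly above the
  cutoff, so an E-value-filtered census must reproduce the truth counts
  exactly.
* **Planted outliers**: a fraction (default 0.25) of P/OP genomes get
  their repertoire multiplied by 0.5 and a Metabolism→Information shift
  of 0.15 probability mass (the two deltas cancel by construction) —
  reduced proteomes that trade metabolic for informational domains, the
  canonical reductive-evolution signature.

All sampling flows from one `numpy` generator seeded by the config; the
same seed reproduces byte-identical output files. The expansion layer
uses a second stream derived from the seed so truth counts are identical
whether or not files are written.

**What the generator does not emulate.** Real proteomes have
phylogenetic autocorrelation (related genomes share repertoires), FSF
occupancy is strongly heterogeneous (ancient FSFs are near-universal),
group labels correlate with composition within superkingdoms, and
parasite reduction is a continuum rather than a two-point mixture.
Passing tests on synthetic cohorts therefore demonstrate that the
pipeline recovers *planted* structure of realistic shape and scale —
exact truth recovery through the I/O and census layers, correct test
calibration, detectable planted effects — not that any biological claim
about real proteomes is reproduced beyond the packaged scheme-level pool
statistics, which are exact.

## Numerical and design choices

* E-value comparison inclusive at the cutoff; strict parse mode is the
  default for assignment tables (silent data loss is worse than failure);
  a lenient mode skips, logs and counts malformed rows.
* Category labels match case-insensitively after whitespace collapsing
  (abbreviation-heavy labels like "m/tr" invite copy variance); the
  canonical spellings are fixed constants.
* Ordering strings break count ties alphabetically and render them with
  `=`.
* Problem sizes in the test suite and acceptance script (150-genome
  round-trip cohorts, 20 × 100-genome recovery cohorts, 100 replicate
  cohorts for the separation study, 1,000/2,000-replicate calibration
  loops) were chosen as the smallest sizes at which the checked
  properties are statistically stable.

## Known limitations

* The placeholder FSF keys make the packaged scheme unsuitable for
  annotating *real* assignment tables; supply a real scheme TSV for that.
* The Welch implementation targets k small (here k ≤ 3) and moderate
  group sizes; it makes no continuity corrections for tiny `n_i`.
* The outlier screen is per-category univariate; a genome deviating
  mildly in many categories at once will not be flagged.
* `group` (phylum/kingdom) labels in the generator are decorative
  (uniformly assigned within superkingdom) and carry no compositional
  signal.
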