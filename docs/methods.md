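# Methods

## The problem

Venom proteins evolve from non-toxic ancestors by a handful of mechanisms:
duplication of an existing gene followed by neofunctionalization of one copy,
expression-dependent co-option of a single-copy gene into the venom gland,
and — more controversially — emergence of lineage-specific *orphan* genes
with no detectable homologue outside the clade. `venomstrat` classifies the
predominant venom proteins of a focal species into these categories by
combining four evidence layers: orthology (an orthogroup table over a set of
genomes), phylogeny (a rooted species tree), expression (tissue-resolved
TPM), and proteomics (venom proteins matched to gene models).

## Gene-age assignment (phylostratigraphy)

Each internal vertex on the path from the tree root to the focal leaf is a
*lineage node*; node 1 is the deepest split (focal lineage vs the outgroup),
indices increase toward the focal leaf. An orthogroup containing the focal
species is dated to the deepest node whose sister clade contributes at least
one member species — equivalently the MRCA of the focal species and all
member species. The rule rests on the Dollo assumption that an orthogroup
arises once and may be lost repeatedly; consequently the assignment is a
lower bound on age: losses or missing annotations can make an origin look
younger (larger node index), never older. The oracle-equivalence and
simulation tests verify both the rule itself (exhaustive presence patterns
against a brute-force MRCA computation) and the bound (lossy simulations).

Three sentinels complete the partition: `focal_exclusive` (an orthogroup
whose members are all focal genes — a stratum of its own, reported as the
node after the last split), `unassigned` (a focal gene clustered into no
orthogroup; counted per gene, not per orthogroup), and `not_applicable`
(orthogroups without focal members; excluded from all focal summaries).
With outgroup-limited sampling, "node 1" necessarily means *node 1 or
earlier*; the deepest available split is reported. Polytomies below the
root are accepted and contribute one stratum per vertex; a trifurcating
root is rejected as unrooted.

## Identification and selection of venom proteins

Venom-gland proteins are tied to gene models through 12-column tabular
similarity hits. A hit survives at `evalue <= 1e-40` and query coverage
`>= 0.90` (both inclusive; coverage is the aligned query span over the query
length, the common convention when no finer definition is available). The
best surviving hit by bitscore wins; ties break to lower e-value, then to
lexicographic gene id, so outputs are reproducible. A *predominant* toxin is
a proteome-confirmed gene with venom-gland expression `>= 500` TPM and
`>= 4`-fold gland-over-body enrichment in at least one sex. "At least one
sex" is the only combination rule consistent with a single predominant set
containing sex-variable members; each sex is always compared with its own
body sample, and sexes are never pooled. A zero-body-tissue denominator
yields `+inf` fold change (the candidate passes): a transcript expressed
only in the venom gland is the strongest enrichment signal. An optional
housekeeping flag removes candidates only when their expression is
body-dominated in every sex (fold < 1) — the quantitative pattern overrides
the annotation.

The family-percentage summary (the composition view) uses a separate,
laxer inclusion rule: proteome-confirmed transcripts above 1 TPM (strict),
with families under 1% of the included TPM pooled into "others"; a family
at exactly 1% keeps its name. The two thresholds are deliberately different
(strict `>` for inclusion, inclusive `>=` for the predominant filter),
mirroring how each is conventionally stated.

## Copy classes and mechanism labels

Copy class is computed against the focal species' members of the gene's
orthogroup: `single_copy` (exactly one focal member), `multi_copy` with one
vs several members present in the venom (venom presence = proteomic
confirmation), or `no_orthogroup`. The mechanism label is then a pure
decision table:

| stratum | copy class | mechanism |
|---|---|---|
| deep node (homologues beyond the restricted clade) | single copy | co-option |
| deep node | multi copy | duplication + neofunctionalization |
| restricted node / focal-exclusive / no orthogroup | any | lineage-specific orphan |

"Restricted" nodes are the splits whose sister clades lie inside the focal
lineage's own (here: the split to the other robber fly); by default the
shallowest split is restricted. Restricted-node toxins are labelled orphans
even when multi-copy — their duplication history is real but their ancestry
outside the lineage is undetectable — and the copy class is retained
alongside so the two-way view (ancient vs lineage-restricted) remains
recoverable. Inconsistent pairs (a clustered copy class with an
`unassigned` stratum, or vice versa) are hard errors.

Toxin names follow the rational nomenclature `U-<Family>-<Sc><gene><paralog>`
(e.g. `U-Asilidin_2-Dd2a`): within a family, distinct orthogroups get
successive gene indices ordered by descending venom-gland expression, and
co-orthogroup paralogs share the index with successive letters.

## TE overlap

TE intervals are intersected with gene spans (exons plus introns) via an
interval tree; each (gene, TE) pair with at least `min_overlap_bp` (default
1) produces a hit annotated with its region (exon / intron / both) from the
exon–intron partition. Strand is ignored; nested or overlapping TE records
are not merged, so class breakdowns stay faithful to the input. Property
tests check equality with brute-force pairwise intersection on random
instances and monotonicity in the overlap threshold.

## Synthetic data

The generator emulates the statistical structure of the study design at
desk scale, on the 14-taxon demo topology (two lepidopteran outgroups, the
mosquito clade, the gall midge, five non-asilid brachycerans, two robber
flies; focal = *Dasypogon diadema*, five splits on the focal path):

- **Gene-family histories.** Families are born at stated lineage nodes with
  one gene per descendant species; default birth counts
  (150/18/3/5/8 across nodes 1–5 plus 3 focal-exclusive, with 30
  unclustered focal orphans) keep the per-node proportions of a
  genome-scale orthology analysis at roughly 1/50 size, large enough for
  stable counts and small enough for second-scale tests. Focal families
  gain terminal paralogs with probability 0.25; non-focal copies are lost
  independently (default 0.1). Focal genes are never lost, so toxin
  designation and per-gene summaries stay well defined; the Dollo-bound
  tests depend only on non-focal losses, which this choice does not affect.
- **Expression.** Negative-binomial counts (variance `m + d·m²`,
  default dispersion `d = 0.3`, the usual bulk-RNA-seq overdispersion
  scale) for six samples (venom gland / proboscis / body × male / female).
  Expected counts scale with effective length, so TPM normalization is
  exercised realistically. Toxin genes get a venom-gland mean of
  `baseline × enrichment` (defaults 60 × 200), placing toxins far above
  both the 500-TPM and 4-fold thresholds and non-toxins far below.
- **Proteomics.** Each toxin is detected independently with probability
  `detection_prob` (default 1.0) and yields a strong hit (e-value 1e-60,
  coverage 0.99); optional decoy hits sit above any sane threshold and must
  be filtered out.
- **TE placement.** Each designated TE gene (default 11 of 30 toxins) gets
  one TE inside its intron; the remaining budget lands in intergenic gaps,
  so the seeded overlap truth is exact.

What the generator does *not* emulate: assembly and annotation error,
isoform structure (one transcript per gene), shared protein families across
orthogroups, allelic variation in pooled samples, sequence-level homology
(FASTA content is random), and realistic TE landscapes. Passing recovery
tests therefore demonstrate correctness of the inference layer given its
inputs, not robustness to upstream artefacts.

## Numerical and reporting choices

- Internal coordinates are 0-based half-open everywhere; conversion happens
  only at I/O boundaries (GFF3 and RepeatMasker are 1-based closed on
  disk). The conversion is involutive and property-tested.
- TPM columns must sum to 1e6 within 1e-6 relative tolerance; all-zero
  count vectors are an error rather than a silent zero division.
- Reported per-stratum percentages round half-away-from-zero to whole
  percents (7,471 of 8,878 → 84%).
- Reruns of the pipeline with the same config are byte-identical; the run
  log carries versions, thresholds and input checksums but no timestamps.
- Seeds are explicit everywhere; derived seeds are small fixed offsets of
  the bundle seed so each simulator is independently reproducible.

## Problem sizes used in checks

The consistency computations over published count tables run on an encoded
8,878-orthogroup table (instantaneous). Recovery checks use 200 simulated
families (loss-free and at 20% loss), a 30-toxin near-noise-free bundle
(dispersion 1e-6, full detection) for end-to-end precision/recall, and 50
random tables for threshold-monotonicity sweeps. These sizes give exact or
binomially-bounded expectations while keeping the whole suite in seconds.

## Known limitations

- Orthogroup dating is bounded, not exact, under gene loss; no attempt is
  made at probabilistic gene-tree/species-tree reconciliation.
- One gene model per gene (longest-CDS isoform) — isoform-aware TE overlap
  or expression is out of scope.
- The proteomic layer consumes a similarity-hit table; spectra, FDR
  estimation and protein inference happen upstream.
- Family assignment relies on a user-supplied gene→family map; without one,
  families degenerate to per-gene labels and family percentages are
  per-gene percentages.
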