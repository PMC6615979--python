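# venomstrat

Phylostratigraphic classification of venom-protein origins from comparative
genomic and proteotranscriptomic evidence.

`venomstrat` answers, for a venomous focal species with a sequenced genome:
*where do its venom proteins come from?* Given per-species gene sets, an
orthogroup table, a rooted species tree, tissue-resolved expression,
proteomic evidence and repeat annotations, it

1. dates every focal orthogroup/gene to a **lineage node** (phylostratum):
   the deepest split on the root→focal path whose sister clade contains a
   homologue — i.e. the MRCA of the focal species and all orthogroup
   members;
2. selects the **predominant venom proteins**: proteome-confirmed genes
   with venom-gland expression ≥ 500 TPM and ≥ 4-fold gland-over-body
   enrichment in at least one sex;
3. classifies each one's **copy number** (single-copy; multi-copy with one
   or several orthogroup members in the venom; no orthogroup) and
   **origin mechanism** — single-gene co-option, duplication +
   neofunctionalization, or lineage-specific orphan;
4. intersects toxin loci with **transposable-element** annotations; and
5. emits publication-style tables (per-node orthogroup counts, toxin
   classification, expression heatmap matrix, TE summary).

For gene-level TPM, `TPM_i = 10^6 · (c_i/ℓ_i) / Σ_j (c_j/ℓ_j)` with read
counts `c` and effective lengths `ℓ`. Orthogroup dating follows the Dollo
convention (an orthogroup arises once, may be lost repeatedly), so assigned
ages are lower bounds.

A fully seeded synthetic-data module simulates gene-family birth/duplication/
loss on the tree, venom-gland-enriched negative-binomial expression, partial
proteome detection and TE placement with known ground truth, so the entire
pipeline is testable without any downloads.

## Worked example

Generate a synthetic bundle and run the full pipeline on it:

```bash
venomstrat simulate --seed 4 --out demo
# write demo/config.yaml pointing at the bundle files (see docs/methods.md),
# then:
venomstrat run --config demo/config.yaml --out demo_out --seed 4
```

which prints

```
30 predominant toxins of 30 proteome-confirmed candidates; outputs in demo_out
```

and writes `node_summary.tsv`:

```
stratum	label	orthogroups	toxin_orthogroups	top30_orthogroups	percent
1	Node 1	148	15	15	79
2	Node 2	20	5	5	11
3	Node 3	3	1	1	2
4	Node 4	5	0	0	3
5	Node 5	8	3	3	4
focal_exclusive	Node 6	3	2	2	2
total	total	187	26	26	100
```

Reading: of 187 orthogroups containing the focal species, 148 (79%) trace
back to the deepest split (ancestral variants already present in the common
ancestor with the outgroup), 8 are shared only with the focal species'
closest relative, and 3 are exclusive to the focal species; 26 orthogroups
contain a venom protein. `toxin_table.tsv` lists each candidate with its
nomenclature name, stratum, copy class and mechanism, e.g.

```
gene_id	name	...	stratum	copy_class	mechanism
Dd_Dasy_g00154	U-...-Dd1a	1	multi_copy_one_in_venom	duplication_neofunctionalization
Dd_Dasy_g00207	U-...-Dd1a	2	single_copy	co_option
```

The standalone utilities are also exposed:

```bash
venomstrat coverage --read-pairs 167137385 --read-length 120 --genome-size 450000000
# -> 89.140	89   (theoretical sequencing depth, exact and rounded)
```

## Layout

- `src/venomstrat/formats_io.py` — readers/writers (orthogroup TSV, Newick,
  GFF3, RepeatMasker out/GFF, 12-column similarity hits, quant tables)
- `src/venomstrat/phylostrat.py` — lineage nodes, orthogroup/gene dating,
  per-stratum counts
- `src/venomstrat/expression.py` — TPM, fold changes, family percentages
- `src/venomstrat/toxin_pipeline.py` — proteome matching, predominant
  filter, copy/mechanism classification, nomenclature
- `src/venomstrat/te_overlap.py` — TE/gene interval intersection
- `src/venomstrat/synthetic_data.py` — seeded generators with ground truth
- `src/venomstrat/report.py`, `cli.py` — summaries, config-driven pipeline,
  `venomstrat` command

See `docs/methods.md` for the model, assumptions, parameter defaults and
known limitations.
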