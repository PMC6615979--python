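"""Seeded synthetic input bundles with known ground truth.

The generator emulates the statistical structure of a venom
proteotranscriptomics study: gene families are born at known nodes of the
focal species' lineage and propagate to all descendant species, with
optional focal-terminal duplications and random losses in non-focal leaves;
a designated subset of focal genes are "toxins" with venom-gland-enriched
negative-binomial expression; toxins are detected in a simulated proteome
with a given probability; TE intervals are placed so that a chosen subset of
toxin genes carries a repeat in its intron.

Every operation takes an explicit seed and is byte-reproducible.  Default
parameters mirror a desk-scale venomics study: a 14-taxon tree with two
outgroup lepidopterans, family birth counts proportional to what genome-wide
orthology clustering typically yields across those splits, 30 designated
toxins of which 11 carry a TE.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import formats_io
from .expression import ExpressionMatrix, SEXES, TISSUES
from .formats_io import GeneModel, OrthogroupTable, SimilarityHit, TEAnnotation
from .phylostrat import FOCAL_EXCLUSIVE, LineageNode, SpeciesTree, focal_lineage

logger = logging.getLogger(__name__)

#: 14-taxon demo topology: two lepidopteran outgroups, the mosquito clade,
#: the gall midge, non-asilid brachycerans, and the two robber flies with
#: Dasypogon diadema as the focal leaf.
DEFAULT_TREE_NEWICK = (
    "((Bombyx_mori,Danaus_plexippus),"
    "(((Aedes_aegypti,Culex_quinquefasciatus),(Anopheles_gambiae,Anopheles_darlingi)),"
    "(Mayetiola_destructor,((Dasypogon_diadema,Proctacanthus_coquillettii),"
    "((Drosophila_grimshawi,(Drosophila_melanogaster,Drosophila_simulans)),"
    "(Teleopsis_dalmanni,Lucilia_cuprina))))));"
)
DEFAULT_FOCAL = "Dasypogon_diadema"


def default_tree() -> SpeciesTree:
    return SpeciesTree.from_newick(DEFAULT_TREE_NEWICK, focal=DEFAULT_FOCAL)


def _default_families() -> Dict[object, int]:
    # birth counts per stratum, roughly 1/50 of a genome-scale study
    return {1: 150, 2: 18, 3: 3, 4: 5, 5: 8, FOCAL_EXCLUSIVE: 3}


@dataclass
class SimulationParams:
    """Knobs of the generator; defaults are the study conditions emulated.

    ``families_per_node`` maps lineage-node index (or ``FOCAL_EXCLUSIVE``)
    to the number of gene families born there.  ``dispersion`` is the
    negative-binomial overdispersion (variance = m + dispersion * m^2).
    """

    families_per_node: Dict[object, int] = field(default_factory=_default_families)
    dup_prob: float = 0.25          # probability a family gains focal paralogs
    max_extra_copies: int = 2       # focal paralogs added per duplicated family
    loss_prob: float = 0.1          # per non-focal gene loss probability
    n_unassigned: int = 30          # focal genes clustered into no orthogroup
    n_toxins: int = 30              # designated venom proteins
    n_te_toxins: int = 11           # toxins carrying a TE in their intron
    baseline_mean: float = 60.0     # mean read count per kb, non-enriched
    enrichment: float = 200.0       # venom-gland fold enrichment of toxins
    dispersion: float = 0.3         # NB overdispersion
    detection_prob: float = 1.0     # per-toxin proteome detection probability

    def validate(self) -> None:
        if any(c < 0 for c in self.families_per_node.values()):
            raise ValueError("family counts must be >= 0")
        if not 0 <= self.loss_prob < 1:
            raise ValueError("loss_prob must be in [0, 1)")
        if not 0 <= self.dup_prob <= 1:
            raise ValueError("dup_prob must be in [0, 1]")
        if not 0 <= self.detection_prob <= 1:
            raise ValueError("detection_prob must be in [0, 1]")


@dataclass
class GeneTruth:
    gene_id: str
    family: Optional[str]           # None for unclustered orphans
    species: str
    duplication_branch: Optional[str]
    lost: bool


@dataclass
class SimulationTruth:
    """Ground truth of one simulated history."""

    families: Dict[str, object]          # family id -> birth node
    genes: Dict[str, GeneTruth]
    toxin_genes: Set[str]
    te_genes: Set[str]
    unassigned_genes: Set[str]
    params: SimulationParams
    seed: int
    focal: str

    def surviving(self, species: Optional[str] = None) -> List[GeneTruth]:
        return [
            g for g in self.genes.values()
            if not g.lost and (species is None or g.species == species)
        ]

    def focal_gene_ids(self) -> List[str]:
        return [g.gene_id for g in self.surviving(self.focal)]

    def to_json(self) -> str:
        payload = {
            "families": {k: v for k, v in self.families.items()},
            "genes": {k: dataclasses.asdict(v) for k, v in self.genes.items()},
            "toxin_genes": sorted(self.toxin_genes),
            "te_genes": sorted(self.te_genes),
            "unassigned_genes": sorted(self.unassigned_genes),
            "params": dataclasses.asdict(self.params),
            "seed": self.seed,
            "focal": self.focal,
        }
        params = payload["params"]
        params["families_per_node"] = {str(k): v for k, v in params["families_per_node"].items()}
        return json.dumps(payload, indent=1, sort_keys=True)


def _abbrev(species: str) -> str:
    parts = species.split("_")
    return (parts[0][:1] + parts[-1][:1]).capitalize() if len(parts) > 1 else species[:2]


def simulate_history(
    tree: SpeciesTree,
    params: Optional[SimulationParams] = None,
    seed: int = 0,
) -> Tuple[Dict[str, List[str]], SimulationTruth]:
    """Simulate gene-family births, duplications and losses on *tree*.

    A family born at node *k* starts with one gene in the focal species and
    one in every species of the sister clades at nodes >= k (the clade below
    the birth vertex).  Focal genes are never lost, so the focal gene set
    stays non-empty and toxin designation is well defined; losses hit
    non-focal copies independently.  Returns the per-species surviving gene
    sets and the :class:`SimulationTruth`.
    """
    params = params or SimulationParams()
    params.validate()
    rng = np.random.default_rng(seed)
    lineage = focal_lineage(tree)
    valid_keys = {n.index for n in lineage} | {FOCAL_EXCLUSIVE}
    bad = set(params.families_per_node) - valid_keys
    if bad:
        raise ValueError(f"birth nodes not on the focal lineage: {sorted(bad)}")

    focal = tree.focal
    counter: Dict[str, int] = {}

    def new_gene(species: str) -> str:
        counter[species] = counter.get(species, 0) + 1
        return f"{_abbrev(species)}_{species[:4]}_g{counter[species]:05d}"

    families: Dict[str, object] = {}
    genes: Dict[str, GeneTruth] = {}
    fam_no = 0
    for key in sorted(params.families_per_node, key=str):
        for _ in range(params.families_per_node[key]):
            fam_no += 1
            fam_id = f"FAM{fam_no:05d}"
            families[fam_id] = key
            if key == FOCAL_EXCLUSIVE:
                present = {focal}
                n_focal_copies = 2  # an orthogroup needs clustered members
            else:
                present = {focal} | set().union(
                    *(n.sister_clade for n in lineage if n.index >= key)
                )
                n_focal_copies = 1
            if rng.random() < params.dup_prob:
                n_focal_copies += int(rng.integers(1, params.max_extra_copies + 1))
            for sp in sorted(present):
                n_copies = n_focal_copies if sp == focal else 1
                for c in range(n_copies):
                    gid = new_gene(sp)
                    lost = sp != focal and rng.random() < params.loss_prob
                    genes[gid] = GeneTruth(
                        gene_id=gid,
                        family=fam_id,
                        species=sp,
                        duplication_branch="terminal" if (sp == focal and c > 0) else None,
                        lost=lost,
                    )

    unassigned: Set[str] = set()
    for _ in range(params.n_unassigned):
        gid = new_gene(focal)
        genes[gid] = GeneTruth(gid, None, focal, None, False)
        unassigned.add(gid)

    focal_genes = [g.gene_id for g in genes.values() if g.species == focal and not g.lost]
    if not focal_genes:
        raise ValueError("parameters produced an empty focal gene set")
    if params.n_toxins > len(focal_genes):
        raise ValueError("n_toxins exceeds the focal gene count")
    toxins = set(rng.choice(sorted(focal_genes), size=params.n_toxins, replace=False))
    if params.n_te_toxins > params.n_toxins:
        raise ValueError("n_te_toxins exceeds n_toxins")
    te_genes = set(rng.choice(sorted(toxins), size=params.n_te_toxins, replace=False))

    truth = SimulationTruth(
        families=families,
        genes=genes,
        toxin_genes=toxins,
        te_genes=te_genes,
        unassigned_genes=unassigned,
        params=params,
        seed=seed,
        focal=focal,
    )
    gene_sets = {
        sp: sorted(g.gene_id for g in truth.surviving(sp)) for sp in tree.leaves
    }
    logger.info(
        "simulated %d families, %d genes (%d focal, %d toxins)",
        len(families), len(genes), len(focal_genes), len(toxins),
    )
    return gene_sets, truth


def simulate_orthogroups(
    truth: SimulationTruth,
    misassignment_rate: float = 0.0,
    seed: Optional[int] = None,
) -> OrthogroupTable:
    """One orthogroup per family with surviving members; optional noise.

    With ``misassignment_rate > 0`` each clustered gene is independently
    moved to a random other orthogroup; moves are logged.  Unclustered
    orphan genes never enter the table.
    """
    if not truth.genes:
        raise ValueError("empty simulation truth")
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    species_list = sorted({g.species for g in truth.genes.values()})

    entries: Dict[str, Dict[str, List[str]]] = {}
    fam_to_og = {}
    for i, fam_id in enumerate(sorted(truth.families), start=1):
        og_id = f"OG{i:07d}"
        members: Dict[str, List[str]] = {}
        for g in truth.genes.values():
            if g.family == fam_id and not g.lost:
                members.setdefault(g.species, []).append(g.gene_id)
        members = {sp: sorted(gs) for sp, gs in members.items() if gs}
        if members:
            entries[og_id] = members
            fam_to_og[fam_id] = og_id

    if misassignment_rate > 0:
        og_ids = sorted(entries)
        moved = 0
        for og_id in og_ids:
            for sp in list(entries[og_id]):
                for gid in list(entries[og_id][sp]):
                    if rng.random() < misassignment_rate:
                        others = [o for o in og_ids if o != og_id and o in entries]
                        target = others[int(rng.integers(len(others)))]
                        entries[og_id][sp].remove(gid)
                        entries[target].setdefault(sp, []).append(gid)
                        moved += 1
        # drop emptied orthogroups
        for og_id in list(entries):
            if not any(entries[og_id].values()):
                del entries[og_id]
        logger.info("misassigned %d genes across orthogroups", moved)

    table = OrthogroupTable(
        entries={og: {sp: sorted(gs) for sp, gs in m.items() if gs} for og, m in entries.items()},
        species_list=species_list,
    )
    table.validate()
    return table


SAMPLE_IDS = ("vg_male", "vg_female", "pb_male", "pb_female", "bt_male", "bt_female")


def _sample_meta() -> pd.DataFrame:
    tissue = {"vg": "venom_gland", "pb": "proboscis", "bt": "body"}
    rows = {s: (tissue[s.split("_")[0]], s.split("_")[1]) for s in SAMPLE_IDS}
    return pd.DataFrame(
        {"tissue": {s: t for s, (t, _) in rows.items()},
         "sex": {s: x for s, (_, x) in rows.items()}}
    )


def simulate_expression(
    truth: SimulationTruth,
    baseline_mean: Optional[float] = None,
    enrichment: Optional[float] = None,
    dispersion: Optional[float] = None,
    seed: Optional[int] = None,
) -> ExpressionMatrix:
    """Negative-binomial counts for the 6 samples (3 tissues x 2 sexes).

    Toxin genes get ``baseline_mean * enrichment`` as their venom-gland mean
    in both sexes; every other (gene, sample) mean is ``baseline_mean``.
    Expected counts scale with effective length (reads per kb), so TPM is
    length-corrected realistically.
    """
    p = truth.params
    baseline_mean = p.baseline_mean if baseline_mean is None else baseline_mean
    enrichment = p.enrichment if enrichment is None else enrichment
    dispersion = p.dispersion if dispersion is None else dispersion
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng(truth.seed + 2 if seed is None else seed)

    genes = sorted(truth.focal_gene_ids())
    eff_len = pd.Series(
        rng.integers(300, 3000, size=len(genes)).astype(float), index=genes
    )
    is_toxin = np.array([g in truth.toxin_genes for g in genes])

    samples = _sample_meta()
    counts = {}
    for sample in SAMPLE_IDS:
        mean = np.full(len(genes), baseline_mean)
        if samples.loc[sample, "tissue"] == "venom_gland":
            mean = np.where(is_toxin, baseline_mean * enrichment, mean)
        mean = mean * (eff_len.to_numpy() / 1000.0)
        r = 1.0 / dispersion
        draws = rng.negative_binomial(n=r, p=r / (r + mean))
        counts[sample] = draws.astype(float)
    counts_df = pd.DataFrame(counts, index=genes)
    return ExpressionMatrix.from_counts(counts_df, eff_len, samples)


def simulate_proteome(
    truth: SimulationTruth,
    detection_prob: Optional[float] = None,
    seed: Optional[int] = None,
    n_decoys: int = 0,
    decoy_evalue: float = 1e-10,
) -> List[SimilarityHit]:
    """Similarity hits for proteomically detected toxins (plus optional decoys).

    Each toxin gene is detected independently with *detection_prob*; a
    detected gene yields a strong hit (e-value 1e-60, coverage 0.99).
    Decoys are weak hits (above any sane e-value threshold) against random
    non-toxin genes, useful to exercise threshold filtering.
    """
    p = truth.params.detection_prob if detection_prob is None else detection_prob
    rng = np.random.default_rng(truth.seed + 3 if seed is None else seed)
    hits: List[SimilarityHit] = []
    for gene in sorted(truth.toxin_genes):
        if rng.random() < p:
            hits.append(
                SimilarityHit(
                    query_id=f"VP_{gene}",
                    subject_id=gene,
                    evalue=1e-60,
                    query_coverage=0.99,
                    bitscore=float(rng.integers(300, 600)),
                )
            )
    if n_decoys:
        non_toxins = sorted(set(truth.focal_gene_ids()) - truth.toxin_genes)
        targets = rng.choice(non_toxins, size=min(n_decoys, len(non_toxins)), replace=False)
        for i, gene in enumerate(targets):
            hits.append(
                SimilarityHit(
                    query_id=f"VPdecoy_{i:03d}",
                    subject_id=str(gene),
                    evalue=decoy_evalue,
                    query_coverage=0.5,
                    bitscore=60.0,
                )
            )
    return hits


def simulate_gene_models(
    truth: SimulationTruth,
    seed: Optional[int] = None,
    genes_per_scaffold: int = 10,
) -> List[GeneModel]:
    """Two-exon gene models for every surviving focal gene, tiled on scaffolds.

    Layout per gene: exon(400) - intron(200) - exon(400), then a 1 kb
    intergenic gap; coordinates are deterministic given the gene order.
    """
    models = []
    for i, gid in enumerate(sorted(truth.focal_gene_ids())):
        scaf = f"scaffold_{i // genes_per_scaffold + 1}"
        offset = (i % genes_per_scaffold) * 2000
        models.append(
            GeneModel(
                gene_id=gid,
                species=truth.focal,
                seq_id=scaf,
                strand="+",
                span=(offset, offset + 1000),
                exons=((offset, offset + 400), (offset + 600, offset + 1000)),
                protein_length=800 // 3,
            )
        )
    return models


def simulate_te(
    truth: SimulationTruth,
    gene_models: Sequence[GeneModel],
    n_te: Optional[int] = None,
    seed: Optional[int] = None,
) -> List[TEAnnotation]:
    """TE intervals placed so exactly the designated ``te_genes`` overlap.

    Each TE gene receives one TE inside its intron; any remaining budget up
    to *n_te* is placed in intergenic gaps (never overlapping a gene span).
    """
    rng = np.random.default_rng(truth.seed + 4 if seed is None else seed)
    classes = [("LTR", "Unknown"), ("LTR", "Gypsy"), ("LINE", "L2"), ("DNA", "Mariner")]
    weights = np.array([0.45, 0.2, 0.2, 0.15])
    by_id = {m.gene_id: m for m in gene_models}
    tes: List[TEAnnotation] = []
    for gid in sorted(truth.te_genes):
        model = by_id[gid]
        intron = model.introns[0]
        cls, fam = classes[int(rng.choice(len(classes), p=weights))]
        tes.append(TEAnnotation(model.seq_id, (intron[0] + 40, intron[0] + 160), cls, fam))

    n_te = len(tes) + 9 if n_te is None else n_te
    extra = n_te - len(tes)
    if extra < 0:
        raise ValueError(f"n_te={n_te} smaller than the {len(tes)} designated TE genes")
    for j in range(extra):
        # 1 kb gap after each gene: [span_end + 200, span_end + 800) is safe
        model = by_id[sorted(by_id)[int(rng.integers(len(by_id)))]]
        start = model.span[1] + 200 + int(rng.integers(0, 300))
        cls, fam = classes[int(rng.choice(len(classes), p=weights))]
        tes.append(TEAnnotation(model.seq_id, (start, start + 300), cls, fam))
    tes.sort(key=lambda t: (t.seq_id, t.interval))
    return tes


# ---------------------------------------------------------------------------
# bundle assembly


@dataclass
class Bundle:
    """A complete in-memory input bundle plus its ground truth."""

    tree: SpeciesTree
    truth: SimulationTruth
    gene_sets: Dict[str, List[str]]
    table: OrthogroupTable
    models: List[GeneModel]
    tes: List[TEAnnotation]
    matrix: ExpressionMatrix
    hits: List[SimilarityHit]

    @property
    def query_lengths(self) -> Dict[str, int]:
        return {h.query_id: 100 for h in self.hits}


def generate_bundle(
    params: Optional[SimulationParams] = None,
    seed: int = 0,
    tree: Optional[SpeciesTree] = None,
) -> Bundle:
    """Run every simulator with seeds derived from *seed* and collect the bundle."""
    tree = tree or default_tree()
    gene_sets, truth = simulate_history(tree, params, seed=seed)
    table = simulate_orthogroups(truth)
    matrix = simulate_expression(truth)
    hits = simulate_proteome(truth)
    models = simulate_gene_models(truth)
    tes = simulate_te(truth, models)
    return Bundle(tree, truth, gene_sets, table, models, tes, matrix, hits)


_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def write_bundle(bundle: Bundle, outdir) -> Dict[str, object]:
    """Write every bundle component in its external format; returns the paths.

    Layout: ``tree.nwk``, ``orthogroups.tsv``, ``genes.gff3``,
    ``repeats.out``, ``proteome_hits.tsv``, ``quant/<sample>.tsv``,
    ``proteins/<species>.fasta``, ``truth.json``.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    (outdir / "quant").mkdir(parents=True, exist_ok=True)
    (outdir / "proteins").mkdir(exist_ok=True)

    paths: Dict[str, object] = {}
    paths["tree"] = outdir / "tree.nwk"
    Path(paths["tree"]).write_text(bundle.tree.as_newick() + "\n")

    paths["orthogroups"] = outdir / "orthogroups.tsv"
    formats_io.write_orthogroups(bundle.table, paths["orthogroups"])

    paths["gff3"] = outdir / "genes.gff3"
    formats_io.write_gff3(bundle.models, paths["gff3"])

    paths["repeats"] = outdir / "repeats.out"
    formats_io.write_repeat_annotations(bundle.tes, paths["repeats"])

    paths["hits"] = outdir / "proteome_hits.tsv"
    formats_io.write_similarity_hits(bundle.hits, bundle.query_lengths, paths["hits"])

    quant_paths = {}
    matrix = bundle.matrix
    for sample in matrix.tpm.columns:
        df = pd.DataFrame(
            {
                "transcript_id": matrix.tpm.index,
                "length": matrix.effective_lengths.to_numpy().astype(int),
                "effective_length": matrix.effective_lengths.to_numpy(),
                "est_counts": matrix.counts[sample].to_numpy(),
                "tpm": matrix.tpm[sample].to_numpy(),
            }
        )
        qp = outdir / "quant" / f"{sample}.tsv"
        df.to_csv(qp, sep="\t", index=False)
        quant_paths[sample] = qp
    paths["quant"] = quant_paths

    rng = np.random.default_rng(bundle.truth.seed + 5)
    protein_paths = {}
    for sp, gene_ids in bundle.gene_sets.items():
        records = []
        for gid in gene_ids:
            length = 266 if sp == bundle.truth.focal else 150
            seq = "".join(rng.choice(_AA, size=length))
            records.append(SeqRecord(Seq(seq), id=gid, description=""))
        fp = outdir / "proteins" / f"{sp}.fasta"
        SeqIO.write(records, str(fp), "fasta")
        protein_paths[sp] = fp
    paths["proteins"] = protein_paths

    # venom-protein queries for the similarity hits
    vp_records = [
        SeqRecord(Seq("".join(rng.choice(_AA, size=100))), id=q, description="")
        for q in sorted(bundle.query_lengths)
    ]
    paths["venom_proteins"] = outdir / "venom_proteins.fasta"
    SeqIO.write(vp_records, str(paths["venom_proteins"]), "fasta")

    paths["truth"] = outdir / "truth.json"
    Path(paths["truth"]).write_text(bundle.truth.to_json() + "\n")
    return paths
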