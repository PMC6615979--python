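"""Publication-style summaries and full-pipeline orchestration.

``node_summary`` produces the per-split orthogroup accounting (shared
orthogroups, toxin orthogroups, predominant-toxin orthogroups, per-stratum
percentages), ``heatmap_export`` the genes-by-samples TPM matrix in fixed
column order, ``theoretical_coverage`` the sequencing-depth utility, and
``run_pipeline`` the config-driven end-to-end run with a machine-readable
log.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd
import yaml

from . import __version__, formats_io, phylostrat, te_overlap, toxin_pipeline
from .expression import ExpressionMatrix, matrix_from_quant
from .phylostrat import FOCAL_EXCLUSIVE, SpeciesTree
from .toxin_pipeline import ToxinRecord

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "max_evalue": 1e-40,
    "min_qcov": 0.90,
    "min_tpm": 500.0,
    "min_fold": 4.0,
    "fig_tpm": 1.0,       # strict > threshold of the family-percentage view
    "fig_percent": 1.0,   # families below this share pool into "others"
}


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def node_summary(
    table: formats_io.OrthogroupTable,
    tree: SpeciesTree,
    toxin_ogs: Optional[Set[str]] = None,
    top30_ogs: Optional[Set[str]] = None,
    unassigned_genes: int = 0,
) -> pd.DataFrame:
    """Per-stratum orthogroup counts with percentages and a totals row.

    One row per lineage node plus the focal-exclusive stratum (labelled as
    the next node number) and a ``total`` row.  ``percent`` is each
    stratum's share of the focal-containing orthogroups, rounded
    half-away-from-zero to a whole percent.  The unassigned focal-gene count
    rides along in ``DataFrame.attrs["unassigned_genes"]``.
    """
    lineage = phylostrat.focal_lineage(tree)
    shared = phylostrat.count_per_stratum(table, tree)
    with_toxin = (
        phylostrat.count_per_stratum(table, tree, restrict_to=toxin_ogs)
        if toxin_ogs is not None
        else {k: 0 for k in shared}
    )
    with_top30 = (
        phylostrat.count_per_stratum(table, tree, restrict_to=top30_ogs)
        if top30_ogs is not None
        else {k: 0 for k in shared}
    )
    total = sum(shared.values())

    strata: List = [n.index for n in lineage] + [FOCAL_EXCLUSIVE]
    labels = [f"Node {n.index}" for n in lineage] + [f"Node {len(lineage) + 1}"]
    rows = []
    for stratum, label in zip(strata, labels):
        n = shared[stratum]
        rows.append(
            {
                "stratum": stratum,
                "label": label,
                "orthogroups": n,
                "toxin_orthogroups": with_toxin[stratum],
                "top30_orthogroups": with_top30[stratum],
                "percent": round_half_away(100.0 * n / total) if total else 0,
            }
        )
    rows.append(
        {
            "stratum": "total",
            "label": "total",
            "orthogroups": total,
            "toxin_orthogroups": sum(with_toxin.values()),
            "top30_orthogroups": sum(with_top30.values()),
            "percent": 100 if total else 0,
        }
    )
    df = pd.DataFrame(rows)
    df.attrs["unassigned_genes"] = unassigned_genes
    return df


HEATMAP_COLUMNS = ["Vg-m", "Vg-f", "Pb-m", "Pb-f", "Bt-m", "Bt-f"]
_HEATMAP_KEYS = [
    ("venom_gland", "male"), ("venom_gland", "female"),
    ("proboscis", "male"), ("proboscis", "female"),
    ("body", "male"), ("body", "female"),
]


def heatmap_export(matrix: ExpressionMatrix, records: Sequence[ToxinRecord]) -> pd.DataFrame:
    """Genes x 6-sample TPM matrix with stratum/family metadata columns.

    Raw TPM values (any log transform belongs to plotting); columns in the
    fixed order venom gland, proboscis, body tissue, male before female; rows
    sorted by descending venom-gland TPM.
    """
    rows = {}
    for rec in records:
        values = []
        for tissue, sex in _HEATMAP_KEYS:
            cols = matrix.sample_ids(tissue=tissue, sex=sex)
            values.append(float(matrix.tpm.loc[rec.gene_id, cols].sum()) if cols else 0.0)
        rows[rec.gene_id] = values + [rec.stratum, rec.family]
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=HEATMAP_COLUMNS + ["stratum", "family"]
    )
    order = df[["Vg-m", "Vg-f"]].max(axis=1).sort_values(ascending=False).index
    return df.loc[order]


def theoretical_coverage(
    read_pairs: int, read_length_nt: int, genome_size_bp: int
) -> Tuple[float, int]:
    """Theoretical sequencing depth: ``pairs * 2 * read_length / genome size``.

    Returns the exact fold value and its whole-number rounding for reports.
    """
    if read_pairs <= 0 or read_length_nt <= 0 or genome_size_bp <= 0:
        raise ValueError("all coverage inputs must be > 0")
    fold = read_pairs * 2 * read_length_nt / genome_size_bp
    return fold, round_half_away(fold)


# ---------------------------------------------------------------------------
# configuration-driven pipeline


@dataclass
class RunResult:
    node_table: pd.DataFrame
    records: List[ToxinRecord]          # all proteome-confirmed candidates
    predominant: List[ToxinRecord]
    te_summary: te_overlap.TESummary
    heatmap: pd.DataFrame
    paths: Dict[str, Path]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _validate_config(cfg: dict, base: Path) -> Dict[str, object]:
    inputs = cfg.get("inputs")
    if not isinstance(inputs, dict):
        raise ValueError("config: missing 'inputs' section")
    required = ["tree", "orthogroups", "gff3", "repeats", "hits", "venom_proteins", "quant"]
    missing = [k for k in required if k not in inputs]
    if missing:
        raise ValueError(f"config: missing input entries {missing}")
    resolved: Dict[str, object] = {}
    for key in required[:-1]:
        p = (base / inputs[key]).resolve() if not Path(inputs[key]).is_absolute() else Path(inputs[key])
        if not p.exists():
            raise FileNotFoundError(f"config input {key!r}: {p} does not exist")
        resolved[key] = p
    quant = {}
    for sample, spec in inputs["quant"].items():
        p = Path(spec["path"])
        p = (base / p).resolve() if not p.is_absolute() else p
        if not p.exists():
            raise FileNotFoundError(f"quant sample {sample!r}: {p} does not exist")
        quant[sample] = {"path": p, "tissue": spec["tissue"], "sex": spec["sex"]}
    resolved["quant"] = quant
    thresholds = dict(DEFAULT_THRESHOLDS)
    for key, val in (cfg.get("thresholds") or {}).items():
        if key not in thresholds:
            raise ValueError(f"config: unknown threshold {key!r}")
        if not isinstance(val, (int, float)) or isinstance(val, bool):
            raise ValueError(f"config: threshold {key!r} must be numeric, got {val!r}")
        thresholds[key] = float(val)
    resolved["thresholds"] = thresholds
    return resolved


def run_pipeline(config, out_dir=None, seed: int = 0) -> RunResult:
    """Execute the full origin-inference pipeline from a config mapping/file.

    The config names every input file (tree, orthogroup table, GFF3 gene
    models, repeat annotations, venom-protein FASTA, similarity hits, quant
    tables with tissue/sex labels), the focal species and thresholds.  All
    inputs are validated before any computation.  Outputs (tab-separated
    tables plus ``run_log.json``) are written under *out_dir* when given;
    reruns with identical inputs are byte-identical.
    """
    from Bio import SeqIO

    if not isinstance(config, dict):
        base = Path(config).parent
        config = load_config(config)
    else:
        base = Path(".")
    focal = config.get("focal")
    if not focal:
        raise ValueError("config: missing 'focal' species")
    resolved = _validate_config(config, base)
    thresholds = resolved["thresholds"]

    tree = formats_io.read_newick(resolved["tree"], focal=focal)
    table = formats_io.read_orthogroups(resolved["orthogroups"])
    models = formats_io.read_gff3(resolved["gff3"], species=focal)
    tes = formats_io.read_repeat_annotations(resolved["repeats"])
    query_lengths = {
        r.id: len(r.seq) for r in SeqIO.parse(str(resolved["venom_proteins"]), "fasta")
    }
    hits = formats_io.read_similarity_hits(resolved["hits"], query_lengths)
    quant = resolved["quant"]
    matrix = matrix_from_quant(
        {s: q["path"] for s, q in quant.items()},
        {s: (q["tissue"], q["sex"]) for s, q in quant.items()},
    )

    housekeeping: Set[str] = set()
    hk_path = config.get("housekeeping")
    if hk_path:
        housekeeping = {
            ln.strip() for ln in Path(base / hk_path).read_text().splitlines() if ln.strip()
        }
    family_map: Dict[str, str] = {}
    fm_path = config.get("family_map")
    if fm_path:
        for ln in Path(base / fm_path).read_text().splitlines():
            if ln.strip():
                gene, fam = ln.split("\t")[:2]
                family_map[gene.strip()] = fam.strip()

    match = toxin_pipeline.match_proteome(
        hits, max_evalue=thresholds["max_evalue"], min_qcov=thresholds["min_qcov"]
    )
    records = toxin_pipeline.build_records(
        matrix, match.matched, family_map=family_map, housekeeping_genes=housekeeping
    )
    records = toxin_pipeline.housekeeping_exclusion(records)
    predominant = toxin_pipeline.predominant_filter(
        records, min_tpm=thresholds["min_tpm"], min_fold=thresholds["min_fold"]
    )
    venom_genes = {r.gene_id for r in records}
    toxin_pipeline.classify_records(
        records, table, tree, venom_genes,
        species_code=config.get("species_code", "Dd"),
    )

    og_of_gene = table.gene_to_orthogroup()
    toxin_ogs = {og_of_gene[r.gene_id] for r in records if r.gene_id in og_of_gene}
    top_ogs = {og_of_gene[r.gene_id] for r in predominant if r.gene_id in og_of_gene}
    focal_genes = [m.gene_id for m in models]
    gene_strata = phylostrat.assign_gene_strata(focal_genes, table, tree)
    n_unassigned = sum(1 for a in gene_strata if a.stratum == phylostrat.UNASSIGNED)

    node_table = node_summary(
        table, tree, toxin_ogs=toxin_ogs, top30_ogs=top_ogs, unassigned_genes=n_unassigned
    )
    predominant_ids = {r.gene_id for r in predominant}
    te_hits = te_overlap.annotate_te([m for m in models if m.gene_id in predominant_ids], tes)
    te_sum = te_overlap.summarize_te(te_hits, predominant_ids)
    for rec in records:
        rec.te_present = any(h.gene_id == rec.gene_id for h in te_hits)
    heat = heatmap_export(matrix, predominant)

    paths: Dict[str, Path] = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths["node_summary"] = out / "node_summary.tsv"
        nt = node_table.copy()
        nt.to_csv(paths["node_summary"], sep="\t", index=False)
        paths["toxins"] = out / "toxin_table.tsv"
        _records_frame(records, predominant_ids).to_csv(paths["toxins"], sep="\t", index=False)
        paths["heatmap"] = out / "heatmap.tsv"
        heat.to_csv(paths["heatmap"], sep="\t", index_label="gene_id")
        paths["te_summary"] = out / "te_summary.tsv"
        pd.DataFrame(
            [{"te_class": c, "n_genes": n} for c, n in te_sum.genes_per_class.items()]
            + [{"te_class": "any", "n_genes": te_sum.n_genes_with_te}]
        ).to_csv(paths["te_summary"], sep="\t", index=False)
        paths["run_log"] = out / "run_log.json"
        log = {
            "version": __version__,
            "seed": seed,
            "focal": focal,
            "thresholds": thresholds,
            "input_checksums": {
                k: _sha256(v) for k, v in resolved.items() if isinstance(v, Path)
            },
            "n_orthogroups": table.n_orthogroups,
            "n_gene_models": len(models),
            "n_proteome_queries": len(match.matched) + len(match.unmatched),
            "n_matched": len(match.matched),
            "n_candidates": len(records),
            "n_predominant": len(predominant),
            "n_unassigned_genes": n_unassigned,
        }
        paths["run_log"].write_text(json.dumps(log, indent=1, sort_keys=True) + "\n")

    return RunResult(
        node_table=node_table,
        records=records,
        predominant=predominant,
        te_summary=te_sum,
        heatmap=heat,
        paths=paths,
    )


def _records_frame(records: Sequence[ToxinRecord], predominant_ids: Set[str]) -> pd.DataFrame:
    rows = []
    for r in sorted(records, key=lambda r: (-r.max_vg_tpm, r.gene_id)):
        rows.append(
            {
                "gene_id": r.gene_id,
                "name": r.name,
                "family": r.family,
                "orthogroup": r.orthogroup_id or "",
                "stratum": r.stratum,
                "copy_class": r.copy_class,
                "mechanism": r.mechanism,
                "vg_tpm_male": round(r.vg_tpm.get("male", 0.0), 3),
                "vg_tpm_female": round(r.vg_tpm.get("female", 0.0), 3),
                "body_tpm_male": round(r.body_tpm.get("male", 0.0), 3),
                "body_tpm_female": round(r.body_tpm.get("female", 0.0), 3),
                "fold_male": round(r.fold.get("male", 0.0), 3)
                if math.isfinite(r.fold.get("male", 0.0)) else "inf",
                "fold_female": round(r.fold.get("female", 0.0), 3)
                if math.isfinite(r.fold.get("female", 0.0)) else "inf",
                "predominant": r.gene_id in predominant_ids,
                "te_present": r.te_present,
            }
        )
    return pd.DataFrame(rows)
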