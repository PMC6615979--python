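"""Venom-protein identification and evolutionary classification.

The pipeline stages implemented here:

1. *Proteome matching* — venom-gland proteins are tied to annotated gene
   models through similarity hits filtered at a strict threshold (e-value
   <= 1e-40 and query coverage >= 90% by default); the best surviving hit
   by bitscore wins, with deterministic tie-breaking.
2. *Predominant-toxin selection* — a putative toxin is "predominant" when it
   is proteome-confirmed, reaches >= 500 TPM in the venom gland and is
   >= 4-fold enriched over body tissue in at least one sex.
3. *Copy-number classification* — single-copy vs multi-copy (one or several
   orthogroup members secreted in venom) vs no orthogroup at all.
4. *Mechanism labelling* — each toxin is explained as ancient single-gene
   co-option, duplication followed by neofunctionalization, or a
   lineage-specific orphan with no homologue outside the focal clade.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

from . import phylostrat
from .expression import SEXES, fold_change
from .formats_io import OrthogroupTable, SimilarityHit
from .phylostrat import FOCAL_EXCLUSIVE, NOT_APPLICABLE, UNASSIGNED, SpeciesTree, Stratum

logger = logging.getLogger(__name__)

# copy classes
SINGLE_COPY = "single_copy"
MULTI_COPY_ONE_IN_VENOM = "multi_copy_one_in_venom"
MULTI_COPY_MULTI_IN_VENOM = "multi_copy_multi_in_venom"
NO_ORTHOGROUP = "no_orthogroup"
COPY_CLASSES = (SINGLE_COPY, MULTI_COPY_ONE_IN_VENOM, MULTI_COPY_MULTI_IN_VENOM, NO_ORTHOGROUP)

# mechanisms
CO_OPTION = "co_option"
DUPLICATION_NEOFUNCTIONALIZATION = "duplication_neofunctionalization"
LINEAGE_SPECIFIC_ORPHAN = "lineage_specific_orphan"
MECHANISMS = (CO_OPTION, DUPLICATION_NEOFUNCTIONALIZATION, LINEAGE_SPECIFIC_ORPHAN)


@dataclass
class ToxinRecord:
    """One venom-protein candidate and every piece of evidence attached to it."""

    gene_id: str
    family: str
    vg_tpm: Dict[str, float] = field(default_factory=dict)     # sex -> TPM
    body_tpm: Dict[str, float] = field(default_factory=dict)   # sex -> TPM
    fold: Dict[str, float] = field(default_factory=dict)       # sex -> gland/body ratio
    proteome_confirmed: bool = False
    orthogroup_id: Optional[str] = None
    stratum: Optional[Stratum] = None
    copy_class: Optional[str] = None
    mechanism: Optional[str] = None
    te_present: bool = False
    housekeeping: bool = False
    name: Optional[str] = None

    @property
    def max_vg_tpm(self) -> float:
        return max(self.vg_tpm.values(), default=0.0)

    def compute_folds(self) -> None:
        self.fold = {
            sex: fold_change(self.vg_tpm.get(sex, 0.0), self.body_tpm.get(sex, 0.0))
            for sex in set(self.vg_tpm) | set(self.body_tpm)
        }


@dataclass
class ProteomeMatch:
    """Outcome of proteome-to-gene matching: winners plus unmatched queries."""

    matched: Dict[str, str]   # venom protein -> gene id
    unmatched: Set[str]


def match_proteome(
    hits: Sequence[SimilarityHit],
    max_evalue: float = 1e-40,
    min_qcov: float = 0.90,
) -> ProteomeMatch:
    """Assign each venom protein to its best gene model above threshold.

    Hits survive when ``evalue <= max_evalue`` and ``query_coverage >=
    min_qcov`` (both boundaries inclusive).  Among survivors the highest
    bitscore wins; ties break to the lowest e-value, then to the
    lexicographically smallest gene id.  Queries with no surviving hit are
    reported in ``unmatched``.
    """
    by_query: Dict[str, List[SimilarityHit]] = {}
    for hit in hits:
        by_query.setdefault(hit.query_id, []).append(hit)

    matched: Dict[str, str] = {}
    unmatched: Set[str] = set()
    for query, qhits in by_query.items():
        survivors = [
            h for h in qhits if h.evalue <= max_evalue and h.query_coverage >= min_qcov
        ]
        if not survivors:
            unmatched.add(query)
            logger.debug("proteome query %s: no hit passed thresholds", query)
            continue
        best = min(survivors, key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
        matched[query] = best.subject_id
    logger.info(
        "proteome matching: %d matched, %d unmatched queries", len(matched), len(unmatched)
    )
    return ProteomeMatch(matched=matched, unmatched=unmatched)


def predominant_filter(
    records: Iterable[ToxinRecord],
    min_tpm: float = 500.0,
    min_fold: float = 4.0,
) -> List[ToxinRecord]:
    """Keep proteome-confirmed records that pass TPM and fold thresholds.

    A record passes when in *at least one sex* the venom-gland TPM is
    ``>= min_tpm`` and the gland/body fold change is ``>= min_fold``
    (inclusive boundaries).  Output is sorted by maximum venom-gland TPM,
    descending (gene id as deterministic tie-break).
    """
    kept = []
    for rec in records:
        if not rec.proteome_confirmed:
            logger.debug("%s dropped: not proteome-confirmed", rec.gene_id)
            continue
        ok = any(
            rec.vg_tpm.get(sex, 0.0) >= min_tpm and rec.fold.get(sex, 0.0) >= min_fold
            for sex in set(rec.vg_tpm) | set(rec.fold)
        )
        if ok:
            kept.append(rec)
        else:
            logger.debug(
                "%s dropped: vg_tpm=%s fold=%s below (%g TPM, %g-fold)",
                rec.gene_id, rec.vg_tpm, rec.fold, min_tpm, min_fold,
            )
    kept.sort(key=lambda r: (-r.max_vg_tpm, r.gene_id))
    return kept


def housekeeping_exclusion(records: Iterable[ToxinRecord]) -> List[ToxinRecord]:
    """Drop housekeeping-flagged records whose expression is body-dominated.

    A flagged record is excluded only when its gland/body fold change is
    below 1 in every sex — a flagged gene that is nevertheless gland-enriched
    is retained (the quantitative pattern overrides the annotation flag).
    """
    kept = []
    for rec in records:
        if rec.housekeeping and rec.fold and max(rec.fold.values()) < 1.0:
            logger.debug(
                "%s excluded as housekeeping (fold=%s, body-dominated)",
                rec.gene_id, rec.fold,
            )
            continue
        kept.append(rec)
    return kept


def copy_class(
    gene_id: str,
    table: OrthogroupTable,
    venom_genes: Set[str],
    focal_species: str,
    _og_of_gene: Optional[Mapping[str, str]] = None,
) -> str:
    """Copy-number class of one focal gene relative to its orthogroup.

    ``no_orthogroup`` if the gene is unclustered; ``single_copy`` if its
    orthogroup holds exactly one focal gene; otherwise multi-copy, split by
    whether one or several orthogroup members are present in the venom.
    """
    og_of_gene = _og_of_gene if _og_of_gene is not None else table.gene_to_orthogroup()
    og = og_of_gene.get(gene_id)
    if og is None:
        return NO_ORTHOGROUP
    focal_members = table.entries[og].get(focal_species, [])
    if len(focal_members) <= 1:
        return SINGLE_COPY
    in_venom = sum(1 for g in focal_members if g in venom_genes)
    return MULTI_COPY_MULTI_IN_VENOM if in_venom >= 2 else MULTI_COPY_ONE_IN_VENOM


def mechanism_label(
    stratum: Stratum,
    copy_cls: str,
    restricted_from: Optional[int] = None,
) -> str:
    """Origin-mechanism label from (stratum, copy class).

    Decision table:

    * no orthogroup (stratum must be ``unassigned``) -> lineage-specific orphan
    * ``focal_exclusive`` stratum -> lineage-specific orphan
    * stratum index ``>= restricted_from`` (splits whose sister clades lie
      inside the focal lineage's restricted clade, e.g. the asilid-only
      split) -> lineage-specific orphan, whatever the copy class
    * otherwise: single-copy -> co-option; multi-copy -> duplication +
      neofunctionalization.

    *restricted_from* is the smallest node index treated as
    lineage-restricted; ``None`` means no node stratum is restricted.
    """
    if copy_cls not in COPY_CLASSES:
        raise ValueError(f"unknown copy class {copy_cls!r}")
    if copy_cls == NO_ORTHOGROUP:
        if stratum != UNASSIGNED:
            raise ValueError(
                f"no_orthogroup record carries stratum {stratum!r}; expected 'unassigned'"
            )
        return LINEAGE_SPECIFIC_ORPHAN
    if stratum == UNASSIGNED:
        raise ValueError(f"copy class {copy_cls!r} inconsistent with unassigned stratum")
    if stratum == NOT_APPLICABLE:
        raise ValueError("orthogroup without focal member cannot be labelled")
    if stratum == FOCAL_EXCLUSIVE:
        return LINEAGE_SPECIFIC_ORPHAN
    if not isinstance(stratum, int) or stratum < 1:
        raise ValueError(f"invalid stratum {stratum!r}")
    if restricted_from is not None and stratum >= restricted_from:
        return LINEAGE_SPECIFIC_ORPHAN
    if copy_cls == SINGLE_COPY:
        return CO_OPTION
    return DUPLICATION_NEOFUNCTIONALIZATION


def name_toxin(
    activity_prefix: str = "U",
    family: str = "",
    species_code: str = "Dd",
    gene_index: int = 1,
    paralog_letter: str = "a",
) -> str:
    """Rational toxin nomenclature: ``U-Asilidin_3-Dd1a`` and friends."""
    if not family:
        raise ValueError("family must be registered (non-empty)")
    if len(species_code) != 2:
        raise ValueError("species_code must be 2 letters")
    if gene_index < 1:
        raise ValueError("gene_index must be >= 1")
    if len(paralog_letter) != 1 or not paralog_letter.isalpha():
        raise ValueError("paralog_letter must be a single letter")
    return f"{activity_prefix}-{family}-{species_code}{gene_index}{paralog_letter}"


def assign_names(records: Sequence[ToxinRecord], species_code: str = "Dd") -> None:
    """Assign nomenclature strings in place.

    Within each family, distinct orthogroups (and unclustered genes) get
    successive gene indices ordered by descending expression; members of the
    same orthogroup share the index and get successive paralog letters.
    """
    by_family: Dict[str, List[ToxinRecord]] = {}
    for rec in records:
        by_family.setdefault(rec.family, []).append(rec)
    for family, recs in by_family.items():
        recs = sorted(recs, key=lambda r: (-r.max_vg_tpm, r.gene_id))
        index_of: Dict[str, int] = {}
        letters: Dict[str, int] = {}
        next_index = 1
        for rec in recs:
            key = rec.orthogroup_id or f"__solo__{rec.gene_id}"
            if key not in index_of:
                index_of[key] = next_index
                next_index += 1
            letters[key] = letters.get(key, 0) + 1
            rec.name = name_toxin(
                "U", family, species_code, index_of[key],
                chr(ord("a") + letters[key] - 1),
            )


def classify_records(
    records: Sequence[ToxinRecord],
    table: OrthogroupTable,
    tree: SpeciesTree,
    venom_genes: Set[str],
    restricted_from: Optional[int] = None,
    species_code: str = "Dd",
) -> None:
    """Populate stratum, copy class, mechanism and name on each record in place.

    *venom_genes* is the set of focal genes with venom (proteomic) presence,
    used to distinguish the two multi-copy classes.  *restricted_from*
    defaults to the shallowest lineage node (the split to the focal species'
    closest sampled relative), below which homology is considered
    lineage-restricted.
    """
    lineage = phylostrat.focal_lineage(tree)
    if restricted_from is None:
        restricted_from = lineage[-1].index if lineage else None
    og_of_gene = table.gene_to_orthogroup()
    strata = {
        a.unit_id: a.stratum
        for a in phylostrat.assign_gene_strata([r.gene_id for r in records], table, tree)
    }
    for rec in records:
        rec.orthogroup_id = og_of_gene.get(rec.gene_id)
        rec.stratum = strata[rec.gene_id]
        rec.copy_class = copy_class(
            rec.gene_id, table, venom_genes, tree.focal, _og_of_gene=og_of_gene
        )
        rec.mechanism = mechanism_label(rec.stratum, rec.copy_class, restricted_from)
    assign_names(records, species_code=species_code)


def build_records(
    matrix,
    matched: Mapping[str, str],
    family_map: Optional[Mapping[str, str]] = None,
    housekeeping_genes: Optional[Set[str]] = None,
    transcripts_of_gene: Optional[Mapping[str, Sequence[str]]] = None,
) -> List[ToxinRecord]:
    """Create one :class:`ToxinRecord` per proteome-matched gene.

    Expression is pulled from *matrix* per sex for venom gland and body
    tissue (gene TPM = sum over the gene's transcripts; by default the
    transcript id equals the gene id).  *family_map* names each gene's
    protein family; unmapped genes fall back to their orthogroup-agnostic
    gene id.
    """
    housekeeping_genes = housekeeping_genes or set()
    from .expression import BODY, VENOM_GLAND

    records = []
    for gene_id in sorted(set(matched.values())):
        transcripts = (
            list(transcripts_of_gene.get(gene_id, [gene_id]))
            if transcripts_of_gene
            else [gene_id]
        )
        family = (family_map or {}).get(gene_id, gene_id)
        rec = ToxinRecord(
            gene_id=gene_id,
            family=family,
            proteome_confirmed=True,
            housekeeping=gene_id in housekeeping_genes,
        )
        for sex in SEXES:
            rec.vg_tpm[sex] = matrix.gene_tpm(transcripts, VENOM_GLAND, sex)
            rec.body_tpm[sex] = matrix.gene_tpm(transcripts, BODY, sex)
        rec.compute_folds()
        records.append(rec)
    return records
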