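"""Readers and writers for the external formats the pipeline consumes.

Everything is normalized at the I/O boundary: genomic coordinates become
0-based half-open internally (GFF3 and RepeatMasker are 1-based closed on
disk), orthogroup tables become :class:`OrthogroupTable`, similarity hits get
their query coverage computed from the alignment span.  Readers reject
malformed records with an error rather than dropping them, and log the number
of records parsed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import gffutils
import pandas as pd

from .phylostrat import SpeciesTree

logger = logging.getLogger(__name__)

Interval = Tuple[int, int]


# ---------------------------------------------------------------------------
# coordinate conversion


def to_zero_based(start1: int, end1: int) -> Interval:
    """1-based closed -> 0-based half-open."""
    if start1 < 1 or end1 < start1:
        raise ValueError(f"invalid 1-based closed interval ({start1}, {end1})")
    return (start1 - 1, end1)


def to_one_based(start0: int, end0: int) -> Interval:
    """0-based half-open -> 1-based closed (inverse of :func:`to_zero_based`)."""
    if start0 < 0 or end0 <= start0:
        raise ValueError(f"invalid 0-based half-open interval ({start0}, {end0})")
    return (start0 + 1, end0)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GeneModel:
    """One protein-coding gene locus (coordinates 0-based half-open).

    ``introns`` is derived: the complement of the exons within the gene span.
    Exons are stored in ascending coordinate order regardless of strand.
    """

    gene_id: str
    species: str
    seq_id: str
    strand: str
    span: Interval
    exons: Tuple[Interval, ...]
    protein_length: int

    def __post_init__(self):
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")
        if self.protein_length <= 0:
            raise ValueError(f"{self.gene_id}: protein_length must be > 0")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene without exons")
        exons = sorted(self.exons)
        if tuple(exons) != self.exons:
            object.__setattr__(self, "exons", tuple(exons))
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = e
        if self.span[0] > self.exons[0][0] or self.span[1] < self.exons[-1][1]:
            raise ValueError(f"{self.gene_id}: span does not cover all exons")

    @property
    def introns(self) -> Tuple[Interval, ...]:
        out = []
        cursor = self.span[0]
        for s, e in self.exons:
            if s > cursor:
                out.append((cursor, s))
            cursor = e
        if cursor < self.span[1]:
            out.append((cursor, self.span[1]))
        return tuple(out)


@dataclass
class OrthogroupTable:
    """Orthogroup id -> (species -> member gene ids).

    Invariants (checked by :meth:`validate`): each gene appears in at most
    one orthogroup, member species are drawn from ``species_list``, and no
    orthogroup is empty.
    """

    entries: Dict[str, Dict[str, List[str]]]
    species_list: List[str]

    def validate(self) -> None:
        seen: Dict[str, str] = {}
        known = set(self.species_list)
        for og_id, members in self.entries.items():
            total = 0
            for sp, genes in members.items():
                if sp not in known:
                    raise ValueError(f"{og_id}: unknown species column {sp!r}")
                for g in genes:
                    if g in seen:
                        raise ValueError(
                            f"gene {g!r} appears in both {seen[g]} and {og_id}"
                        )
                    seen[g] = og_id
                total += len(genes)
            if total == 0:
                raise ValueError(f"orthogroup {og_id} is empty")

    @property
    def n_orthogroups(self) -> int:
        return len(self.entries)

    def genes_of(self, species: str) -> List[str]:
        return [
            g
            for members in self.entries.values()
            for g in members.get(species, [])
        ]

    def gene_to_orthogroup(self) -> Dict[str, str]:
        return {
            g: og_id
            for og_id, members in self.entries.items()
            for genes in members.values()
            for g in genes
        }


@dataclass(frozen=True)
class SimilarityHit:
    """One similarity-search hit of a venom protein against a gene model."""

    query_id: str
    subject_id: str
    evalue: float
    query_coverage: float
    bitscore: float

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not 0.0 <= self.query_coverage <= 1.0:
            raise ValueError("query_coverage must be in [0, 1]")


@dataclass(frozen=True)
class TEAnnotation:
    """One repeat-masker interval (0-based half-open) with its TE classification."""

    seq_id: str
    interval: Interval
    te_class: str
    te_family: str

    def __post_init__(self):
        if self.interval[0] < 0 or self.interval[0] >= self.interval[1]:
            raise ValueError(f"invalid TE interval {self.interval}")
        if not self.te_class:
            raise ValueError("te_class must be non-empty")


# ---------------------------------------------------------------------------
# orthogroup table I/O


def read_orthogroups(path) -> OrthogroupTable:
    """Read a tab-separated orthogroup table (orthology-clusterer dialect).

    Header row: species names (an optional leading orthogroup-id column
    header such as ``Orthogroup`` is recognised).  Data rows:
    ``OG_id<TAB>comma-separated genes per species``; blank cells mean the
    species has no member.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: missing header row") from None
        rows = [row for row in reader if any(cell.strip() for cell in row)]

    if not header or not any(h.strip() for h in header):
        raise ValueError(f"{path}: missing header row")

    if rows and len(rows[0]) == len(header):
        species = [h.strip() for h in header[1:]]
    elif rows and len(rows[0]) == len(header) + 1:
        species = [h.strip() for h in header]
    elif header[0].strip().lower() in ("orthogroup", "og", ""):
        species = [h.strip() for h in header[1:]]
    else:
        species = [h.strip() for h in header]

    entries: Dict[str, Dict[str, List[str]]] = {}
    for i, row in enumerate(rows, start=2):
        if len(row) != len(species) + 1:
            raise ValueError(
                f"{path}:{i}: expected {len(species) + 1} columns, got {len(row)}"
            )
        og_id = row[0].strip()
        members = {}
        for sp, cell in zip(species, row[1:]):
            genes = [g.strip() for g in cell.split(",") if g.strip()]
            members[sp] = genes
        entries[og_id] = members

    table = OrthogroupTable(entries=entries, species_list=list(species))
    table.validate()
    logger.info("read %d orthogroups (%d data rows) from %s", len(entries), len(rows), path)
    return table


def write_orthogroups(table: OrthogroupTable, path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["Orthogroup"] + list(table.species_list))
        for og_id, members in table.entries.items():
            writer.writerow(
                [og_id] + [", ".join(members.get(sp, [])) for sp in table.species_list]
            )


# ---------------------------------------------------------------------------
# species tree


def read_newick(path, focal: Optional[str] = None) -> SpeciesTree:
    """Read a single rooted Newick tree; validates rootedness and leaf uniqueness."""
    text = Path(path).read_text()
    return SpeciesTree.from_newick(text, focal=focal)


# ---------------------------------------------------------------------------
# GFF3 gene models


def read_gff3(path, species: str) -> List[GeneModel]:
    """Read gene/mRNA/exon features from GFF3 into :class:`GeneModel` objects.

    For genes with several mRNAs the isoform with the longest total CDS is
    used.  Protein length is derived from the CDS length (codons); when no
    CDS features are present the exon length is used instead.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )

    # every Parent attribute must resolve
    for feat in db.all_features():
        for pid in feat.attributes.get("Parent", []):
            try:
                db[pid]
            except gffutils.FeatureNotFoundError:
                raise ValueError(
                    f"{feat.featuretype} {feat.id}: unknown parent {pid!r}"
                ) from None

    models = []
    for gene in db.features_of_type("gene"):
        span = to_zero_based(gene.start, gene.end)
        mrnas = list(db.children(gene, featuretype="mRNA"))
        candidates = mrnas if mrnas else [gene]
        best_exons, best_cds = None, -1
        for parent in candidates:
            exons = [to_zero_based(f.start, f.end) for f in db.children(parent, featuretype="exon")]
            cds = sum(f.end - f.start + 1 for f in db.children(parent, featuretype="CDS"))
            if not exons:
                continue
            if cds == 0:
                cds = sum(e - s for s, e in exons)
            if cds > best_cds:
                best_cds, best_exons = cds, sorted(exons)
        if best_exons is None:
            raise ValueError(f"gene {gene.id}: no exon features")
        for s, e in best_exons:
            if s < span[0] or e > span[1]:
                raise ValueError(f"gene {gene.id}: exon ({s}, {e}) outside gene span {span}")
        models.append(
            GeneModel(
                gene_id=gene.id,
                species=species,
                seq_id=gene.seqid,
                strand=gene.strand if gene.strand in ("+", "-") else ".",
                span=span,
                exons=tuple(best_exons),
                protein_length=max(best_cds // 3, 1),
            )
        )
    logger.info("read %d gene models from %s", len(models), path)
    return models


def write_gff3(models: List[GeneModel], path) -> None:
    """Write gene models as gene/mRNA/exon/CDS GFF3 (1-based closed on disk)."""
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            s1, e1 = to_one_based(*m.span)
            attrs = f"ID={m.gene_id}"
            fh.write(
                f"{m.seq_id}\tvenomstrat\tgene\t{s1}\t{e1}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{m.gene_id}.t1"
            fh.write(
                f"{m.seq_id}\tvenomstrat\tmRNA\t{s1}\t{e1}\t.\t{m.strand}\t.\t"
                f"ID={mrna_id};Parent={m.gene_id}\n"
            )
            for i, (s, e) in enumerate(m.exons, start=1):
                es, ee = to_one_based(s, e)
                fh.write(
                    f"{m.seq_id}\tvenomstrat\texon\t{es}\t{ee}\t.\t{m.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
                fh.write(
                    f"{m.seq_id}\tvenomstrat\tCDS\t{es}\t{ee}\t.\t{m.strand}\t0\t"
                    f"ID={mrna_id}.cds{i};Parent={mrna_id}\n"
                )


# ---------------------------------------------------------------------------
# similarity hits (12-column tabular)

_BLAST6_COLS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_similarity_hits(path, query_lengths: Mapping[str, int]) -> List[SimilarityHit]:
    """Read 12-column tabular similarity hits; coverage = aligned span / query length.

    Coverage is computed from the alignment span ``(qend - qstart + 1) / qlen``
    and clamped to [0, 1]; a query missing from *query_lengths* is an error.
    """
    path = Path(path)
    hits = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            rec = dict(zip(_BLAST6_COLS, fields))
            qid = rec["qseqid"]
            if qid not in query_lengths:
                raise ValueError(f"{path}:{lineno}: query {qid!r} missing from query_lengths")
            qstart, qend = int(rec["qstart"]), int(rec["qend"])
            qcov = (qend - qstart + 1) / query_lengths[qid]
            qcov = min(max(qcov, 0.0), 1.0)
            hits.append(
                SimilarityHit(
                    query_id=qid,
                    subject_id=rec["sseqid"],
                    evalue=float(rec["evalue"]),
                    query_coverage=qcov,
                    bitscore=float(rec["bitscore"]),
                )
            )
    logger.info("read %d similarity hits from %s", len(hits), path)
    return hits


def write_similarity_hits(hits: List[SimilarityHit], query_lengths: Mapping[str, int], path) -> None:
    """Write hits back to the 12-column dialect (span reconstructed from coverage)."""
    with Path(path).open("w") as fh:
        for h in hits:
            qlen = query_lengths[h.query_id]
            span = max(int(round(h.query_coverage * qlen)), 1)
            fh.write(
                "\t".join(
                    [
                        h.query_id, h.subject_id, "100.0", str(span), "0", "0",
                        "1", str(span), "1", str(span),
                        f"{h.evalue:g}", f"{h.bitscore:g}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# repeat annotations


def _split_te_class(raw: str) -> Tuple[str, str]:
    if "/" in raw:
        cls, fam = raw.split("/", 1)
        return cls, fam
    return raw, "Unknown"


def read_repeat_annotations(path) -> List[TEAnnotation]:
    """Read RepeatMasker ``.out``-style or GFF repeat annotations (auto-detected).

    ``.out`` dialect: the usual two header lines, then whitespace-separated
    rows with query/begin/end in columns 5-7 and class/family in column 11.
    GFF dialect: column 3 holds ``class/family``.  Output intervals are
    0-based half-open, sorted by (seq_id, start).
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines()]
    nonblank = [ln for ln in lines if ln.strip()]
    if not nonblank:
        return []

    is_gff = nonblank[0].startswith("##gff")
    annos: List[TEAnnotation] = []
    if is_gff:
        for lineno, ln in enumerate(lines, start=1):
            if not ln.strip() or ln.startswith("#"):
                continue
            fields = ln.split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}:{lineno}: expected >=8 GFF columns")
            seq_id, _, te_type, start, end = fields[0], fields[1], fields[2], fields[3], fields[4]
            s1, e1 = int(start), int(end)
            if s1 < 1 or e1 < 1:
                raise ValueError(f"{path}:{lineno}: negative/invalid coordinates")
            cls, fam = _split_te_class(te_type)
            annos.append(TEAnnotation(seq_id, to_zero_based(s1, e1), cls, fam))
    else:
        data_started = False
        for lineno, ln in enumerate(lines, start=1):
            stripped = ln.strip()
            if not stripped:
                continue
            tokens = stripped.split()
            if not data_started:
                # RepeatMasker headers start with "SW" / "score"
                if tokens[0] in ("SW", "score") or not tokens[0].replace(".", "").isdigit():
                    continue
                data_started = True
            if not data_started:
                continue
            if len(tokens) < 11:
                raise ValueError(f"{path}:{lineno}: expected >=11 columns in .out row")
            seq_id = tokens[4]
            s1, e1 = int(tokens[5]), int(tokens[6])
            if s1 < 1 or e1 < 1:
                raise ValueError(f"{path}:{lineno}: negative/invalid coordinates")
            cls, fam = _split_te_class(tokens[10])
            annos.append(TEAnnotation(seq_id, to_zero_based(s1, e1), cls, fam))

    annos.sort(key=lambda a: (a.seq_id, a.interval))
    logger.info("read %d repeat annotations from %s", len(annos), path)
    return annos


def write_repeat_annotations(annos: List[TEAnnotation], path) -> None:
    """Write annotations in the ``.out`` dialect (consumable by the reader)."""
    with Path(path).open("w") as fh:
        fh.write(
            "   SW   perc perc perc  query      position in query     matching"
            "       repeat              position in repeat\n"
            "score   div. del. ins.  sequence   begin  end   (left)   repeat"
            "         class/family       begin  end    (left)   ID\n\n"
        )
        for i, a in enumerate(annos, start=1):
            s1, e1 = to_one_based(*a.interval)
            fh.write(
                f"  500   1.0  0.0  0.0  {a.seq_id}  {s1}  {e1}  (0)  + "
                f" {a.te_family}-like  {a.te_class}/{a.te_family}  1  {e1 - s1 + 1}  (0)  {i}\n"
            )


# ---------------------------------------------------------------------------
# quantification tables

QUANT_COLUMNS = ["transcript_id", "length", "effective_length", "est_counts", "tpm"]


def read_quant_table(path) -> pd.DataFrame:
    """Read one per-sample quant table (transcript_id, length, effective_length,
    est_counts and/or tpm); returns a DataFrame indexed by transcript_id."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    if "transcript_id" not in df.columns:
        raise ValueError(f"{path}: missing transcript_id column")
    if "est_counts" not in df.columns and "tpm" not in df.columns:
        raise ValueError(f"{path}: need est_counts or tpm column")
    return df.set_index("transcript_id")
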