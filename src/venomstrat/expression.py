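"""TPM computation, tissue/sex aggregation and family-percentage summaries.

Expression is quantified as TPM (transcripts per million): per transcript a
length-normalized read rate ``counts_i / effective_length_i``, rescaled so the
rates sum to 10^6 within each sample.  Samples carry a tissue label (venom
gland, proboscis, body) and a sex label; sexes are never pooled implicitly —
every threshold decision is made per sample column.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VENOM_GLAND = "venom_gland"
PROBOSCIS = "proboscis"
BODY = "body"
TISSUES = (VENOM_GLAND, PROBOSCIS, BODY)
SEXES = ("male", "female")


def compute_tpm(counts, effective_lengths) -> np.ndarray:
    """TPM from read counts and effective lengths.

    ``rate_i = counts_i / len_i``; ``TPM_i = 1e6 * rate_i / sum(rate)``.
    Scale-invariant under count scaling; sums to 1e6 exactly (up to float
    rounding).  All-zero counts are an error (normalization undefined).
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(effective_lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and effective_lengths must have the same shape")
    if np.any(lengths <= 0):
        raise ValueError("effective lengths must be > 0")
    if np.any(counts < 0) or not np.all(np.isfinite(counts)):
        raise ValueError("counts must be finite and non-negative")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        raise ValueError("all counts are zero; TPM normalization is undefined")
    return 1e6 * rate / total


def fold_change(tpm_a: float, tpm_b: float) -> float:
    """Ratio ``tpm_a / tpm_b`` with the boundary conventions used throughout:
    ``+inf`` when only the numerator is expressed, ``0`` when neither is."""
    if tpm_a < 0 or tpm_b < 0:
        raise ValueError("TPM values must be non-negative")
    if tpm_b == 0:
        return math.inf if tpm_a > 0 else 0.0
    return tpm_a / tpm_b


@dataclass
class ExpressionMatrix:
    """Transcripts x samples expression container.

    ``tpm`` is the canonical payload (transcripts as rows, sample ids as
    columns); ``samples`` maps each sample id to its tissue and sex.  When
    built from counts, the raw counts and effective lengths are retained.
    """

    tpm: pd.DataFrame
    samples: pd.DataFrame  # index: sample id; columns: tissue, sex
    counts: Optional[pd.DataFrame] = None
    effective_lengths: Optional[pd.Series] = None

    def __post_init__(self):
        missing = set(self.tpm.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples metadata missing for {sorted(missing)}")
        bad_tissue = set(self.samples["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise ValueError(f"unknown tissue labels {sorted(bad_tissue)}")
        sums = self.tpm.sum(axis=0)
        off = sums[(sums - 1e6).abs() > 1.0]  # 1e-6 relative on 1e6
        if len(off):
            raise ValueError(
                f"TPM columns do not sum to 1e6: {dict(off.round(3))}"
            )

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        effective_lengths: pd.Series,
        samples: pd.DataFrame,
    ) -> "ExpressionMatrix":
        lengths = effective_lengths.reindex(counts.index)
        if lengths.isna().any():
            raise ValueError("effective_lengths missing for some transcripts")
        tpm = pd.DataFrame(
            {col: compute_tpm(counts[col].to_numpy(), lengths.to_numpy()) for col in counts},
            index=counts.index,
        )
        return cls(tpm=tpm, samples=samples, counts=counts, effective_lengths=lengths)

    @classmethod
    def from_tpm(cls, tpm: pd.DataFrame, samples: pd.DataFrame) -> "ExpressionMatrix":
        return cls(tpm=tpm, samples=samples)

    # -- lookups ----------------------------------------------------------

    def sample_ids(self, tissue: Optional[str] = None, sex: Optional[str] = None) -> list:
        meta = self.samples
        if tissue is not None:
            meta = meta[meta["tissue"] == tissue]
        if sex is not None:
            meta = meta[meta["sex"] == sex]
        return list(meta.index)

    def tissue_tpm(self, transcript: str, tissue: str, sex: str) -> float:
        """Summed TPM of one transcript over the matching sample columns."""
        cols = self.sample_ids(tissue=tissue, sex=sex)
        if not cols:
            raise ValueError(f"no sample with tissue={tissue!r}, sex={sex!r}")
        return float(self.tpm.loc[transcript, cols].sum())

    def gene_tpm(self, transcripts: Sequence[str], tissue: str, sex: str) -> float:
        """Gene-level TPM = sum of the gene's transcripts' TPM."""
        cols = self.sample_ids(tissue=tissue, sex=sex)
        present = [t for t in transcripts if t in self.tpm.index]
        if not present:
            return 0.0
        return float(self.tpm.loc[present, cols].to_numpy().sum())


@dataclass
class FamilyExpressionSummary:
    """Percent of summed toxin TPM per family and venom-gland sample.

    ``percentages`` rows are family names plus the residual ``others``
    bucket; columns are venom-gland sample ids; each column sums to 100.
    """

    percentages: pd.DataFrame
    n_included: Dict[str, int]

    OTHERS = "others"


def family_percentages(
    matrix: ExpressionMatrix,
    family_map: Mapping[str, str],
    proteome_confirmed: set,
    min_tpm: float = 1.0,
    min_percent: float = 1.0,
) -> FamilyExpressionSummary:
    """Per-family share of venom-gland expression among confirmed transcripts.

    For each venom-gland sample, transcripts that are proteome-confirmed and
    exceed *min_tpm* (strictly) are included; family TPM sums are expressed
    as percentages of the included total, and families below *min_percent*
    (strictly) are pooled into ``others``.  A family sitting exactly at the
    boundary is retained under its own name.
    """
    unmapped = {t for t in proteome_confirmed if t in matrix.tpm.index} - set(family_map)
    if unmapped:
        raise ValueError(f"family_map missing for confirmed transcripts: {sorted(unmapped)}")

    vg_samples = matrix.sample_ids(tissue=VENOM_GLAND)
    if not vg_samples:
        raise ValueError("no venom-gland samples in matrix")

    per_sample = {}
    n_included = {}
    families_seen: list = []
    for sample in vg_samples:
        col = matrix.tpm[sample]
        included = [
            t for t in matrix.tpm.index
            if t in proteome_confirmed and col[t] > min_tpm
        ]
        if not included:
            raise ValueError(
                f"sample {sample!r}: no proteome-confirmed transcript above "
                f"{min_tpm} TPM — nothing to summarize"
            )
        n_included[sample] = len(included)
        sums: Dict[str, float] = {}
        for t in included:
            fam = family_map[t]
            sums[fam] = sums.get(fam, 0.0) + float(col[t])
        total = sum(sums.values())
        pct = {fam: 100.0 * v / total for fam, v in sums.items()}
        named = {fam: p for fam, p in pct.items() if p >= min_percent}
        others = sum(p for fam, p in pct.items() if p < min_percent)
        named[FamilyExpressionSummary.OTHERS] = others
        per_sample[sample] = named
        for fam in named:
            if fam not in families_seen:
                families_seen.append(fam)

    families_sorted = sorted(f for f in families_seen if f != FamilyExpressionSummary.OTHERS)
    index = families_sorted + [FamilyExpressionSummary.OTHERS]
    df = pd.DataFrame(
        {s: [per_sample[s].get(f, 0.0) for f in index] for s in vg_samples},
        index=index,
    )
    return FamilyExpressionSummary(percentages=df, n_included=n_included)


def matrix_from_quant(
    files: Mapping[str, object],
    sample_meta: Mapping[str, tuple],
    use: str = "auto",
) -> ExpressionMatrix:
    """Build an :class:`ExpressionMatrix` from per-sample quant tables.

    *files* maps sample id -> path; *sample_meta* maps sample id ->
    ``(tissue, sex)``.  With ``use="auto"`` counts are preferred (TPM is then
    recomputed); ``use="tpm"`` trusts a precomputed TPM column.
    """
    from .formats_io import read_quant_table

    tables = {s: read_quant_table(p) for s, p in files.items()}
    samples = pd.DataFrame(
        {
            "tissue": {s: meta[0] for s, meta in sample_meta.items()},
            "sex": {s: meta[1] for s, meta in sample_meta.items()},
        }
    ).loc[list(files)]

    first = next(iter(tables.values()))
    have_counts = all("est_counts" in t.columns for t in tables.values())
    if use == "auto":
        use = "counts" if have_counts else "tpm"
    if use == "counts":
        if not have_counts:
            raise ValueError("est_counts column absent; cannot recompute TPM")
        counts = pd.DataFrame({s: t["est_counts"] for s, t in tables.items()})
        eff = first["effective_length"]
        return ExpressionMatrix.from_counts(counts, eff, samples)
    tpm = pd.DataFrame({s: t["tpm"] for s, t in tables.items()})
    return ExpressionMatrix.from_tpm(tpm, samples)
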