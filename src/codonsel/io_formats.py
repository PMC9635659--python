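"""Readers/writers and the stated data-hygiene steps.

Covers the coding-sequence FASTA reader, mutation tables (TSV dialect plus a
minimal genomic-VCF subset mapped to CDS coordinates), expression matrices
with quantile normalization, and confounder tables.  The mutation-quality
filters implement the sequencing post-filters with their literal boundary
semantics: Phred quality strictly greater than 100, mutant-read frequency of
at least 0.90 kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .codon_model import (
    _COMPLEMENT,
    GeneModel,
    GeneValidationError,
    GeneticCode,
    STANDARD_BACTERIAL_CODE,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MutationRecord",
    "read_cds_fasta",
    "write_cds_fasta",
    "read_mutation_table",
    "write_mutation_table",
    "read_vcf_mutations",
    "filter_mutations",
    "annotate_mutation",
    "annotate_mutations",
    "mutations_to_frame",
    "frame_to_mutations",
    "quantile_normalize",
    "read_expression_matrix",
    "expression_summary",
    "read_confounder_table",
]

MUTATION_COLUMNS = ["gene_id", "cds_pos", "ref", "alt", "lineage", "quality", "alt_freq", "annotation"]


@dataclass(frozen=True)
class MutationRecord:
    """One fixed base-pair substitution, in 1-based CDS coordinates."""

    gene_id: str
    cds_pos: int
    ref: str
    alt: str
    lineage: str = ""
    quality: float = np.inf
    alt_freq: float = 1.0
    annotation: Optional[str] = None  # "synonymous" | "nonsynonymous" | None


def read_cds_fasta(
    path, code: GeneticCode = STANDARD_BACTERIAL_CODE, trim_trailing_stop: bool = True
) -> list[GeneModel]:
    """Read in-frame CDSs from FASTA; invalid records are rejected with a logged reason."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    n_records = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        gene_id = rec.id
        if gene_id in seen:
            logger.warning("duplicate gene id %s: record rejected", gene_id)
            continue
        try:
            gene = GeneModel.from_cds(gene_id, str(rec.seq), code, trim_trailing_stop)
        except GeneValidationError as exc:
            logger.warning("rejected CDS: %s", exc)
            continue
        seen.add(gene_id)
        genes.append(gene)
    if n_records == 0:
        logger.warning("no FASTA records found in %s", path)
    return genes


def write_cds_fasta(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.gene_id}\n")
            for i in range(0, g.L, 70):
                fh.write(g.cds[i : i + 70] + "\n")


def mutations_to_frame(records: Iterable[MutationRecord]) -> pd.DataFrame:
    rows = [
        (r.gene_id, r.cds_pos, r.ref, r.alt, r.lineage, r.quality, r.alt_freq, r.annotation)
        for r in records
    ]
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


def frame_to_mutations(df: pd.DataFrame) -> list[MutationRecord]:
    out = []
    for row in df.itertuples(index=False):
        ann = getattr(row, "annotation", None)
        if ann is not None and (isinstance(ann, float) and np.isnan(ann)):
            ann = None
        out.append(
            MutationRecord(
                gene_id=str(row.gene_id),
                cds_pos=int(row.cds_pos),
                ref=str(row.ref),
                alt=str(row.alt),
                lineage=str(row.lineage),
                quality=float(row.quality),
                alt_freq=float(row.alt_freq),
                annotation=None if ann is None else str(ann),
            )
        )
    return out


def write_mutation_table(records: Iterable[MutationRecord], path) -> None:
    mutations_to_frame(records).to_csv(path, sep="\t", index=False)


def read_mutation_table(path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "lineage": str})
    missing = set(MUTATION_COLUMNS[:7]) - set(df.columns)
    if missing:
        raise ValueError(f"mutation table {path} missing columns {sorted(missing)}")
    if "annotation" not in df.columns:
        df["annotation"] = None
    return frame_to_mutations(df)


def read_vcf_mutations(vcf_path, gene_coords_path) -> list[MutationRecord]:
    """Read a minimal VCF 4.2 subset and map genomic to CDS coordinates.

    Uses the fixed columns CHROM/POS/REF/ALT/QUAL and the INFO keys
    ``lineage=`` and ``AF=``.  ``gene_coords_path`` is a TSV with columns
    gene_id, chrom, start, end, strand (1-based inclusive genomic span of
    the CDS); minus-strand genes have ref/alt complemented and positions
    counted from the ``end``.  Positions outside any gene are skipped.
    """
    coords = pd.read_csv(gene_coords_path, sep="\t", dtype={"gene_id": str, "chrom": str})
    records: list[MutationRecord] = []
    n_skipped = 0
    with open(vcf_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, pos, _id, ref, alt, qual = fields[:6]
            pos = int(pos)
            info = dict(
                kv.split("=", 1) for kv in (fields[7].split(";") if len(fields) > 7 else []) if "=" in kv
            )
            hit = coords[(coords["chrom"] == chrom) & (coords["start"] <= pos) & (pos <= coords["end"])]
            if hit.empty:
                n_skipped += 1
                continue
            g = hit.iloc[0]
            if str(g.get("strand", "+")) == "-":
                cds_pos = int(g["end"]) - pos + 1
                ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
            else:
                cds_pos = pos - int(g["start"]) + 1
            records.append(
                MutationRecord(
                    gene_id=str(g["gene_id"]),
                    cds_pos=cds_pos,
                    ref=ref,
                    alt=alt,
                    lineage=info.get("lineage", ""),
                    quality=float(qual) if qual != "." else np.inf,
                    alt_freq=float(info.get("AF", 1.0)),
                )
            )
    if n_skipped:
        logger.info("%d VCF records outside annotated genes skipped", n_skipped)
    return records


def filter_mutations(
    records: Sequence[MutationRecord],
    min_quality: float = 100.0,
    min_alt_freq: float = 0.90,
) -> list[MutationRecord]:
    """Quality post-filters: keep quality > min_quality AND alt_freq ≥ min_alt_freq.

    The boundaries are deliberate: a record at quality exactly 100 is removed,
    one at alt_freq exactly 0.90 is kept.  Order-preserving and idempotent.
    """
    kept: list[MutationRecord] = []
    n_lowq = n_lowf = 0
    for r in records:
        if not r.quality > min_quality:
            n_lowq += 1
            continue
        if r.alt_freq < min_alt_freq:
            n_lowf += 1
            continue
        kept.append(r)
    logger.info(
        "filter_mutations: %d kept, %d removed (quality ≤ %g), %d removed (alt_freq < %g)",
        len(kept), n_lowq, min_quality, n_lowf, min_alt_freq,
    )
    return kept


def annotate_mutation(
    gene: GeneModel, record: MutationRecord, code: GeneticCode = STANDARD_BACTERIAL_CODE
) -> MutationRecord:
    """Classify a substitution as synonymous/nonsynonymous against the ancestral codon.

    Stop-gaining (nonsense) changes are folded into nonsynonymous.
    """
    codon, offset = gene.codon_at(record.cds_pos)
    if codon[offset] != record.ref.upper():
        raise ValueError(
            f"{gene.gene_id} position {record.cds_pos}: ancestral base is "
            f"{codon[offset]}, record says {record.ref}"
        )
    mutant = codon[:offset] + record.alt.upper() + codon[offset + 1 :]
    syn = (not code.is_stop(mutant)) and code.translate(mutant) == code.translate(codon)
    return replace(record, annotation="synonymous" if syn else "nonsynonymous")


def annotate_mutations(
    genes: Sequence[GeneModel],
    records: Sequence[MutationRecord],
    code: GeneticCode = STANDARD_BACTERIAL_CODE,
) -> list[MutationRecord]:
    """Annotate every record; multi-hit ancestral codons are logged.

    Each substitution is interpreted independently against the ancestral
    codon, even when several substitutions (possibly from different
    lineages) strike the same codon.
    """
    by_id = {g.gene_id: g for g in genes}
    hit_codons: dict[tuple[str, int], int] = {}
    out = []
    for r in records:
        gene = by_id.get(r.gene_id)
        if gene is None:
            raise KeyError(f"mutation references unknown gene {r.gene_id}")
        out.append(annotate_mutation(gene, r, code))
        key = (r.gene_id, (r.cds_pos - 1) // 3)
        hit_codons[key] = hit_codons.get(key, 0) + 1
    multi = sum(1 for v in hit_codons.values() if v > 1)
    if multi:
        logger.info("%d ancestral codons hit by more than one substitution", multi)
    return out


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize a genes × samples matrix.

    Every column is mapped onto the reference distribution (the row-wise mean
    of the sorted columns); ties within a column receive the average of the
    reference values across the tied ranks.
    """
    if matrix.shape[1] < 2:
        logger.warning("quantile_normalize: single sample, returning input unchanged")
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("expression values must be non-negative")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # average reference values over tied input values
        s = pd.Series(assigned).groupby(pd.Series(col)).transform("mean")
        out[:, j] = s.to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def read_expression_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def expression_summary(matrix: pd.DataFrame, normalize: bool = True) -> pd.Series:
    """Per-gene mean expression, after quantile normalization by default."""
    m = quantile_normalize(matrix) if normalize and matrix.shape[1] >= 2 else matrix
    return m.mean(axis=1)


def read_confounder_table(path) -> pd.DataFrame:
    """Per-gene confounders: dispensability, essentiality, duplicability, ppi_degree."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    for col in ("essentiality", "duplicability"):
        if col in df.columns:
            df[col] = df[col].astype(float)  # 0/1 coding, NaN = missing
    return df
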