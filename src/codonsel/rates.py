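"""Spectrum- and codon-usage-normalized dN/dS for accumulated substitutions.

A gene of length L with synonymous-substitution probability ``P_S`` offers
``L·P_S`` synonymous and ``L·(1−P_S)`` nonsynonymous opportunity sites under
the mutational spectrum.  dN (dS) is the observed nonsynonymous (synonymous)
substitution count divided by its opportunity, so under neutral accumulation
dN/dS is 1 regardless of how biased the spectrum or the codon usage is.
Counts are pooled over replicate lineages by default; per-lineage rates are
available for lineage-wise summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .codon_model import (
    GeneModel,
    GeneticCode,
    MutationalSpectrum,
    STANDARD_BACTERIAL_CODE,
    estimate_spectrum,
    prob_synonymous,
    prob_synonymous_many,
)
from .io_formats import MutationRecord

__all__ = ["GeneRates", "gene_rates", "genome_wide_ratio", "per_gene_counts", "rates_table"]


@dataclass(frozen=True)
class GeneRates:
    gene_id: str
    m_n: int
    m_s: int
    p_s: float
    dn_novo: Optional[float]
    ds_novo: Optional[float]
    ratio: Optional[float]


def gene_rates(gene: GeneModel, counts: tuple[int, int], p_s: float) -> GeneRates:
    """Per-gene dN, dS and their ratio.

    ``counts`` is (M_N, M_S) from filtered, annotated substitutions.
    dN = M_N / (L·(1−P_S)), dS = M_S / (L·P_S).  A degenerate P_S (0 or 1)
    leaves the corresponding rate undefined (None); the ratio is reported
    only when M_S > 0 so dS is nonzero.
    """
    m_n, m_s = counts
    if m_n < 0 or m_s < 0:
        raise ValueError("substitution counts must be non-negative")
    dn = m_n / (gene.L * (1.0 - p_s)) if p_s < 1.0 else None
    ds = m_s / (gene.L * p_s) if p_s > 0.0 else None
    ratio = dn / ds if (dn is not None and ds is not None and m_s > 0) else None
    return GeneRates(gene.gene_id, m_n, m_s, p_s, dn, ds, ratio)


def genome_wide_ratio(
    genes: Sequence[GeneModel],
    counts: dict[str, tuple[int, int]],
    spectrum: MutationalSpectrum,
    code: GeneticCode = STANDARD_BACTERIAL_CODE,
) -> float:
    """Genome-wide dN/dS: pooled counts over pooled opportunity sites.

    (Σ M_N / Σ L(1−P_S)) / (Σ M_S / Σ L·P_S).  Raises if no synonymous
    substitution was observed genome-wide (the ratio is then undefined).
    """
    freqs = np.vstack([g.codon_freq for g in genes])
    p_s = prob_synonymous_many(freqs, spectrum, code)
    L = np.array([g.L for g in genes], dtype=float)
    m_n = np.array([counts.get(g.gene_id, (0, 0))[0] for g in genes], dtype=float)
    m_s = np.array([counts.get(g.gene_id, (0, 0))[1] for g in genes], dtype=float)
    if m_s.sum() == 0:
        raise ValueError("genome-wide dN/dS undefined: no synonymous substitutions observed")
    dn = m_n.sum() / (L * (1.0 - p_s)).sum()
    ds = m_s.sum() / (L * p_s).sum()
    return float(dn / ds)


def per_gene_counts(
    records: Sequence[MutationRecord], lineage: Optional[str] = None
) -> dict[str, tuple[int, int]]:
    """(M_N, M_S) per gene from annotated records, optionally one lineage only."""
    out: dict[str, list[int]] = {}
    for r in records:
        if lineage is not None and r.lineage != lineage:
            continue
        if r.annotation not in ("synonymous", "nonsynonymous"):
            raise ValueError(f"record {r.gene_id}:{r.cds_pos} is not annotated")
        c = out.setdefault(r.gene_id, [0, 0])
        c[0 if r.annotation == "nonsynonymous" else 1] += 1
    return {g: (c[0], c[1]) for g, c in out.items()}


def rates_table(
    genes: Sequence[GeneModel],
    records: Sequence[MutationRecord],
    spectrum: Optional[MutationalSpectrum] = None,
    code: GeneticCode = STANDARD_BACTERIAL_CODE,
) -> pd.DataFrame:
    """Per-gene rate table from annotated mutations, pooled over lineages.

    When ``spectrum`` is None it is estimated from the observed synonymous
    substitutions, mirroring the usual analysis flow.  Columns: gene_id,
    M_N, M_S, P_S, dN_novo, dS_novo, ratio (NaN where undefined).
    """
    if spectrum is None:
        syn = [r for r in records if r.annotation == "synonymous"]
        spectrum = estimate_spectrum(syn)
    counts = per_gene_counts(records)
    rows = []
    for g in genes:
        p_s = prob_synonymous(g, spectrum, code)
        r = gene_rates(g, counts.get(g.gene_id, (0, 0)), p_s)
        rows.append(
            (r.gene_id, r.m_n, r.m_s, r.p_s,
             np.nan if r.dn_novo is None else r.dn_novo,
             np.nan if r.ds_novo is None else r.ds_novo,
             np.nan if r.ratio is None else r.ratio)
        )
    return pd.DataFrame(rows, columns=["gene_id", "M_N", "M_S", "P_S", "dN_novo", "dS_novo", "ratio"])


def lineage_ratios(
    genes: Sequence[GeneModel],
    records: Sequence[MutationRecord],
    spectrum: Optional[MutationalSpectrum] = None,
    code: GeneticCode = STANDARD_BACTERIAL_CODE,
) -> pd.Series:
    """Genome-wide dN/dS per lineage (the per-replicate summary)."""
    if spectrum is None:
        spectrum = estimate_spectrum([r for r in records if r.annotation == "synonymous"])
    lineages = sorted({r.lineage for r in records})
    vals = {}
    for lin in lineages:
        vals[lin] = genome_wide_ratio(genes, per_gene_counts(records, lineage=lin), spectrum, code)
    return pd.Series(vals, name="dN/dS")
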