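"""Gene- and mutation-level selection statistics: G scores, CAI, C scores.

The normalized G score measures per-gene enrichment of observed over
expected substitution counts, divided by the gene's opportunity sites so
genes of different length and codon usage are comparable:

    G_S = M_S/(L·P_S) · ln(M_S/E_S),   G_N = M_N/(L·(1−P_S)) · ln(M_N/E_N)

with neutral expectations anchored to the genome-wide synonymous total:

    E_S = L·P_S/⟨P_S⟩ · ΣM_S/ΣL,       E_N = (1−P_S)/P_S · E_S.

CAI is the geometric mean of per-codon relative adaptiveness w = f/max f,
with codon frequencies f pooled from the most highly expressed genes.  The
C score of a synonymous change a→m is ln w_m minus the spectrum-weighted
mean of ln w over all synonymous single-step neighbors of a, i.e. the
codon-preference shift relative to the neutral expectation; its expectation
under neutral mutation is exactly zero for every ancestral codon.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .codon_model import (
    CODONS,
    GeneModel,
    GeneticCode,
    MutationalSpectrum,
    STANDARD_BACTERIAL_CODE,
    classify_substitution,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GScores",
    "CodonWeightTable",
    "CScoreRecord",
    "expected_counts",
    "g_scores",
    "g_score_table",
    "build_codon_weights",
    "cai",
    "c_score",
    "synonymous_neighbors",
    "classify_optimality",
]


@dataclass(frozen=True)
class GScores:
    gene_id: str
    e_s: float
    e_n: float
    g_s: float
    g_n: float


def expected_counts(
    table: pd.DataFrame, weighted_mean_ps: bool = False
) -> pd.DataFrame:
    """Neutral expected substitution counts per gene.

    ``table`` needs columns gene_id, L, P_S, M_S.  Adds E_S and E_N.
    ⟨P_S⟩ is the unweighted mean of P_S over genes by default; set
    ``weighted_mean_ps=True`` for the length-weighted alternative.  Genes
    with P_S = 0 are excluded with a warning (E_N would be undefined).
    """
    if len(table) < 2:
        raise ValueError("expected counts need at least 2 genes")
    t = table.copy()
    bad = t["P_S"] <= 0
    if bad.any():
        logger.warning("%d genes with P_S=0 excluded from expected counts", int(bad.sum()))
        t = t[~bad].copy()
    if weighted_mean_ps:
        mean_ps = float(np.average(t["P_S"], weights=t["L"]))
    else:
        mean_ps = float(t["P_S"].mean())
    rate = t["M_S"].sum() / t["L"].sum()
    t["E_S"] = t["L"] * t["P_S"] / mean_ps * rate
    t["E_N"] = (1.0 - t["P_S"]) / t["P_S"] * t["E_S"]
    return t


def _g(m: float, e: float, sites: float) -> float:
    # x·ln(x/e) → 0 as x → 0: zero observed counts give G = 0 by convention
    if m == 0:
        return 0.0
    return m / sites * math.log(m / e)


def g_scores(gene_id: str, m_s: int, m_n: int, e_s: float, e_n: float, L: float, p_s: float) -> GScores:
    """Normalized G scores for one gene (see module docstring for formulas)."""
    if not 0 < p_s < 1:
        raise ValueError(f"{gene_id}: G scores need 0 < P_S < 1, got {p_s}")
    if e_s <= 0 or e_n <= 0:
        raise ValueError(f"{gene_id}: expected counts must be positive")
    return GScores(
        gene_id=gene_id,
        e_s=e_s,
        e_n=e_n,
        g_s=_g(m_s, e_s, L * p_s),
        g_n=_g(m_n, e_n, L * (1.0 - p_s)),
    )


def g_score_table(table: pd.DataFrame, weighted_mean_ps: bool = False) -> pd.DataFrame:
    """Vector version over a rates table (gene_id, L, P_S, M_S, M_N)."""
    t = expected_counts(table, weighted_mean_ps)
    rows = [
        g_scores(r.gene_id, int(r.M_S), int(r.M_N), r.E_S, r.E_N, r.L, r.P_S)
        for r in t.itertuples(index=False)
    ]
    t = t.copy()
    t["G_S"] = [r.g_s for r in rows]
    t["G_N"] = [r.g_n for r in rows]
    return t


@dataclass(frozen=True)
class CodonWeightTable:
    """Relative adaptiveness w = f/max f per codon, from a highly-expressed reference set."""

    w: dict
    f: dict
    reference_genes: tuple

    def ln_w(self, codon: str) -> float:
        return math.log(self.w[codon])


def build_codon_weights(
    genes: Sequence[GeneModel],
    expression: pd.Series,
    top_n: int = 40,
    pseudocount: float = 0.5,
    code: GeneticCode = STANDARD_BACTERIAL_CODE,
) -> CodonWeightTable:
    """Codon weight table from the ``top_n`` most-expressed genes.

    Codon counts are pooled over the reference set; sense codons unobserved
    in the reference receive ``pseudocount`` counts so every weight is
    positive and ln w finite.  Within each synonymous family w = f/max f,
    so the most frequent codon of each family has w = 1.  Rank ties at the
    ``top_n`` boundary are broken lexicographically by gene id (logged).
    """
    by_id = {g.gene_id: g for g in genes}
    expr = expression[expression.index.isin(by_id)]
    if len(expr) < top_n:
        raise ValueError(f"need expression for ≥{top_n} genes, have {len(expr)}")
    ranked = expr.sort_index().sort_values(ascending=False, kind="mergesort")
    if len(ranked) > top_n and ranked.iloc[top_n - 1] == ranked.iloc[top_n]:
        logger.info("expression tie at rank %d broken by gene id", top_n)
    reference = tuple(ranked.index[:top_n])

    counts = {c: 0.0 for c in CODONS if not code.is_stop(c)}
    for gid in reference:
        for codon in by_id[gid].codons():
            counts[codon] += 1.0
    for c in counts:
        if counts[c] == 0.0:
            counts[c] = pseudocount
    total = sum(counts.values())
    f = {c: n / total for c, n in counts.items()}
    w = {}
    for c in counts:
        family = code.synonymous_family(c)
        w[c] = f[c] / max(f[k] for k in family)
    return CodonWeightTable(w=w, f=f, reference_genes=reference)


def cai(gene: GeneModel, weights: CodonWeightTable) -> float:
    """Codon adaptation index: geometric mean of w over the gene's codons."""
    lnw = [math.log(weights.w[c]) for c in gene.codons()]
    return math.exp(sum(lnw) / len(lnw))


def synonymous_neighbors(
    codon: str, code: GeneticCode = STANDARD_BACTERIAL_CODE
) -> list[str]:
    """S_a: sense codons reachable from ``codon`` by one synonymous base change."""
    aa = code.translate(codon)
    out = []
    for i, b in enumerate(codon):
        for alt in "ACGT":
            if alt != b:
                m = codon[:i] + alt + codon[i + 1 :]
                if not code.is_stop(m) and code.translate(m) == aa:
                    out.append(m)
    return out


@dataclass(frozen=True)
class CScoreRecord:
    a: str
    m: str
    w_a: float
    c: float


def c_score(
    a: str,
    m: str,
    weights: CodonWeightTable,
    spectrum: MutationalSpectrum,
    code: GeneticCode = STANDARD_BACTERIAL_CODE,
) -> CScoreRecord:
    """C score of the synonymous change a→m: ln w_m − W_a.

    W_a is the spectrum-weighted mean of ln w over S_a, the synonymous
    single-step neighbors of a, with each neighbor weighted by the spectrum
    probability of the base change that reaches it.  By construction the
    neutral expectation of C over S_a is zero; |S_a| = 1 forces C = 0.
    """
    a, m = a.upper(), m.upper()
    diff = [i for i in range(3) if a[i] != m[i]]
    if len(diff) != 1:
        raise ValueError(f"{a}→{m} is not a single-base change")
    if code.is_stop(a) or code.is_stop(m) or code.translate(a) != code.translate(m):
        raise ValueError(f"{a}→{m} is not a synonymous change")
    neighbors = synonymous_neighbors(a, code)
    probs = np.array(
        [spectrum.prob_of(classify_substitution(a[_diff_pos(a, n)], n[_diff_pos(a, n)])) for n in neighbors]
    )
    total = probs.sum()
    if total <= 0:
        raise ValueError(
            f"spectrum assigns zero probability to every synonymous change from {a}"
        )
    lnw = np.array([weights.ln_w(n) for n in neighbors])
    w_a = float(probs @ lnw / total)
    return CScoreRecord(a=a, m=m, w_a=w_a, c=float(weights.ln_w(m) - w_a))


def _diff_pos(a: str, b: str) -> int:
    return next(i for i in range(3) if a[i] != b[i])


def classify_optimality(cai_values: pd.Series, fraction: float = 0.10) -> pd.Series:
    """Label mutated genes U/M/O from the bottom/middle/top of the CAI distribution.

    The bottom and top floor(fraction·n) genes are unoptimized (U) and
    optimized (O); the rest are moderate (M).  Ties are broken
    deterministically by gene id.  The 5% variant is ``fraction=0.05``.
    """
    n = len(cai_values)
    k = int(math.floor(fraction * n))
    if k < 1:
        raise ValueError(f"{n} genes with fraction {fraction} leaves empty tails")
    order = cai_values.to_frame("cai").reset_index()
    order.columns = ["gene_id", "cai"]
    order = order.sort_values(["cai", "gene_id"], kind="mergesort")
    labels = pd.Series("M", index=order["gene_id"])
    labels.iloc[:k] = "U"
    labels.iloc[-k:] = "O"
    return labels.reindex(cai_values.index)
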