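"""Synthetic mutation-accumulation experiments with known ground truth.

The generator emulates the statistical structure a codon-level selection
analysis assumes: a genome of in-frame, stop-free CDSs whose codon-usage
bias strengthens with expression (so CAI correlates with expression), a
lognormal expression distribution observed through a small replicated
sample matrix, per-gene confounders, and replicate lineages of fixed
base-pair substitutions drawn from a 6-class mutational spectrum with
optional expression-dependent purifying selection on nonsynonymous changes
and optional codon-level (C-score-weighted) selection on synonymous
changes.

Every proposed mutation is interpreted against the ancestral sequence (no
compounding): within a lineage a site can fix at most once, and later
proposals at an already-fixed site are silently skipped.  Proposed =
purged + fixed holds exactly per lineage.  A (config, seed) pair fully
determines all outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .codon_model import (
    BASES,
    CODONS,
    GeneModel,
    GeneticCode,
    MutationalSpectrum,
    STANDARD_BACTERIAL_CODE,
    SUBSTITUTION_CLASSES,
    prob_synonymous_many,
)
from .io_formats import MutationRecord, quantile_normalize
from .selection_scores import build_codon_weights, c_score, synonymous_neighbors

__all__ = ["SimulationConfig", "SimulationTruth", "generate_genome", "simulate_evolution", "simulate"]

#: UV-mutagenesis-like default spectrum (heavy GC→AT, substantial AT→GC);
#: a stated config value in fixed class order, not a transcription of any
#: measured spectrum.
DEFAULT_SPECTRUM = MutationalSpectrum(
    np.array([0.05, 0.05, 0.20, 0.05, 0.50, 0.15]), source="default UV-like"
)

_BASE_CODE = {b: i for i, b in enumerate(BASES)}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated mutation-accumulation experiment.

    Defaults describe a bacterial-scale desk experiment: 500 genes of about
    300 codons, lognormal expression spanning ~3 orders of magnitude,
    strong expression–codon-usage coupling (κ=5), 6 replicate lineages of
    3000 fixed substitutions each, and expression-dependent purifying
    selection purging a nonsynonymous change in the most-expressed gene
    with probability s_N = 0.8.
    """

    n_genes: int = 500
    mean_codons: int = 300
    length_log_sd: float = 0.25
    min_codons: int = 30
    expression_log_mean: float = float(np.log(100.0))
    expression_log_sd: float = 1.5
    n_expression_samples: int = 6
    expression_noise_sd: float = 0.2
    usage_coupling: float = 5.0  # κ: codon-usage bias gain with expression
    spectrum: MutationalSpectrum = field(default_factory=lambda: DEFAULT_SPECTRUM)
    n_mutations: int = 3000  # fixed BPSs per lineage
    n_lineages: int = 6
    selection_nonsyn: float = 0.8  # s_N: purge scale for nonsynonymous changes
    selection_syn: float = 0.0  # s_S: purge scale for C-score-weighted synonymous selection
    syn_selection_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.selection_nonsyn <= 1:
            raise ValueError("selection_nonsyn must be in [0, 1]")
        if self.selection_syn < 0:
            raise ValueError("selection_syn must be ≥ 0")
        if self.n_genes < 2 or self.mean_codons < 2 or self.n_mutations < 1 or self.n_lineages < 1:
            raise ValueError("sizes must be positive (and ≥2 genes)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spectrum"] = self.spectrum.as_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "spectrum" in d and not isinstance(d["spectrum"], MutationalSpectrum):
            d["spectrum"] = MutationalSpectrum.from_dict(d["spectrum"], source="config")
        return cls(**d)


@dataclass
class SimulationTruth:
    """Ground truth recorded beside simulated outputs for recovery tests."""

    config: SimulationConfig
    expression: pd.Series  # per-gene summary used by the generator
    opportunity: pd.DataFrame  # per-gene L, P_S (under the generating spectrum)
    fates: pd.DataFrame  # per-lineage proposed / purged / fixed tallies
    mutations: pd.DataFrame  # the emitted (fixed) mutation table


def _amino_acid_families(code: GeneticCode) -> dict[str, list[str]]:
    fams: dict[str, list[str]] = {}
    for c in CODONS:
        aa = code.translate(c)
        if aa != "*":
            fams.setdefault(aa, []).append(c)
    return fams


def generate_genome(
    config: SimulationConfig,
    code: GeneticCode = STANDARD_BACTERIAL_CODE,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[GeneModel], pd.DataFrame, pd.DataFrame]:
    """Generate (genes, expression matrix, confounder table).

    Gene lengths are lognormal around ``mean_codons``; amino-acid sequences
    are uniform over the 20 residues, so sequences are stop-free by
    construction.  Within each synonymous family one codon is designated
    preferred (chosen once per genome); a gene at expression percentile q
    samples the preferred codon with weight exp(κ·q) against 1 for the
    rest, which couples CAI to expression when κ > 0.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fams = _amino_acid_families(code)
    aas = sorted(fams)
    preferred = {aa: fams[aa][rng.integers(len(fams[aa]))] for aa in aas}

    # true (latent) expression and its percentile drive codon usage
    log_expr = rng.normal(config.expression_log_mean, config.expression_log_sd, config.n_genes)
    q = (np.argsort(np.argsort(log_expr))).astype(float)
    q /= max(config.n_genes - 1, 1)

    lengths = np.maximum(
        config.min_codons,
        np.round(np.exp(rng.normal(np.log(config.mean_codons), config.length_log_sd, config.n_genes))).astype(int),
    )
    if lengths.max() < 1:
        raise ValueError("infeasible length distribution")

    width = len(str(config.n_genes))
    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        aa_seq = rng.choice(aas, size=lengths[i])
        codons = np.empty(lengths[i], dtype=object)
        for aa in np.unique(aa_seq):
            fam = fams[aa]
            w = np.array([np.exp(config.usage_coupling * q[i]) if c == preferred[aa] else 1.0 for c in fam])
            w /= w.sum()
            pos = np.flatnonzero(aa_seq == aa)
            codons[pos] = rng.choice(fam, size=len(pos), p=w)
        genes.append(GeneModel(gene_id=f"g{i+1:0{width}d}", cds="".join(codons)))

    gene_ids = [g.gene_id for g in genes]
    samples = np.exp(
        log_expr[:, None]
        + rng.normal(0.0, config.expression_noise_sd, (config.n_genes, config.n_expression_samples))
    )
    expr = pd.DataFrame(
        samples, index=gene_ids, columns=[f"s{j+1}" for j in range(config.n_expression_samples)]
    )

    confounders = pd.DataFrame(
        {
            "dispensability": np.clip(rng.normal(0.95 - 0.1 * q, 0.05), 0.0, None),
            "essentiality": (rng.random(config.n_genes) < 0.05 + 0.15 * q).astype(float),
            "duplicability": (rng.random(config.n_genes) < 0.3).astype(float),
            "ppi_degree": rng.poisson(2.0 + 8.0 * q),
        },
        index=gene_ids,
    )
    return genes, expr, confounders


def _site_arrays(genes: Sequence[GeneModel]):
    """Flatten the genome into per-site lookup arrays."""
    base = np.concatenate([np.array([_BASE_CODE[b] for b in g.cds], dtype=np.int8) for g in genes])
    site_gene = np.concatenate(
        [np.full(g.L, i, dtype=np.int32) for i, g in enumerate(genes)]
    )
    offset = np.concatenate([np.arange(g.L, dtype=np.int32) for g in genes])
    pos_in_codon = offset % 3
    # codon index at each site: base-4 digits in alphabetical base order
    codon_idx = np.empty(base.shape, dtype=np.int16)
    start = 0
    for g in genes:
        b = base[start : start + g.L].reshape(-1, 3)
        ci = (16 * b[:, 0] + 4 * b[:, 1] + b[:, 2]).astype(np.int16)
        codon_idx[start : start + g.L] = np.repeat(ci, 3)
        start += g.L
    return base, site_gene, offset, pos_in_codon, codon_idx


def _synonymy_lut(code: GeneticCode) -> np.ndarray:
    """syn[codon_idx, pos, alt_base] — True when the change is synonymous."""
    lut = np.zeros((64, 3, 4), dtype=bool)
    for k, codon in enumerate(CODONS):
        if code.is_stop(codon):
            continue
        aa = code.translate(codon)
        for pos in range(3):
            for a, alt in enumerate(BASES):
                if alt == codon[pos]:
                    continue
                mutant = codon[:pos] + alt + codon[pos + 1 :]
                lut[k, pos, a] = (not code.is_stop(mutant)) and code.translate(mutant) == aa
    return lut


def _c_score_lut(
    weights, spectrum: MutationalSpectrum, code: GeneticCode
) -> np.ndarray:
    """C score for every synonymous (codon, pos, alt) change; 0 elsewhere."""
    lut = np.zeros((64, 3, 4))
    for k, codon in enumerate(CODONS):
        if code.is_stop(codon) or not synonymous_neighbors(codon, code):
            continue
        aa = code.translate(codon)
        for pos in range(3):
            for a, alt in enumerate(BASES):
                if alt == codon[pos]:
                    continue
                mutant = codon[:pos] + alt + codon[pos + 1 :]
                if (not code.is_stop(mutant)) and code.translate(mutant) == aa:
                    lut[k, pos, a] = c_score(codon, mutant, weights, spectrum, code).c
    return lut


def simulate_evolution(
    genes: Sequence[GeneModel],
    expression: pd.Series,
    config: SimulationConfig,
    code: GeneticCode = STANDARD_BACTERIAL_CODE,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[MutationRecord], SimulationTruth]:
    """Accumulate fixed substitutions along replicate lineages.

    Each proposal draws a substitution class from the spectrum, then a
    target site uniformly among the genome's bases of that class's source
    pair.  Nonsynonymous proposals are purged with probability
    s_N · (expression rank percentile of the gene); synonymous proposals,
    when s_S > 0, are purged with probability
    min(1, s_S · scale · max(0, −C)) using the C score of the change
    against a weight table built from the top-40 expressed genes.  Fixation
    proceeds until ``n_mutations`` per lineage.  Quality and allele-
    frequency fields are filled so records pass the standard post-filters.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    base, site_gene, offset, pos_in_codon, codon_idx = _site_arrays(genes)
    n_sites = base.size
    if config.n_mutations > n_sites:
        raise ValueError(
            f"n_mutations={config.n_mutations} exceeds the {n_sites} available sites "
            "(mutations are sampled without within-lineage replacement)"
        )
    syn_lut = _synonymy_lut(code)

    expression = expression.reindex([g.gene_id for g in genes])
    if expression.isna().any():
        raise ValueError("expression summary missing for some genes")
    ranks = expression.rank(method="average").to_numpy()
    q_gene = (ranks - 1.0) / max(len(genes) - 1, 1)

    c_lut = None
    if config.selection_syn > 0:
        weights = build_codon_weights(genes, expression, top_n=min(40, len(genes)), code=code)
        c_lut = _c_score_lut(weights, config.spectrum, code)

    is_at_class = np.array([c.source_pair == "AT" for c in SUBSTITUTION_CLASSES])
    # target_lut[class, base] = alt base code (or -1 where class doesn't apply)
    target_lut = np.full((6, 4), -1, dtype=np.int8)
    for j, cls in enumerate(SUBSTITUTION_CLASSES):
        for ref_b, alt_b in cls.changes:
            target_lut[j, _BASE_CODE[ref_b]] = _BASE_CODE[alt_b]
    at_sites = np.flatnonzero((base == _BASE_CODE["A"]) | (base == _BASE_CODE["T"]))
    gc_sites = np.flatnonzero((base == _BASE_CODE["G"]) | (base == _BASE_CODE["C"]))
    if at_sites.size == 0 and config.spectrum.p[is_at_class].sum() > 0:
        raise ValueError("spectrum requires A/T sites but genome has none")
    if gc_sites.size == 0 and config.spectrum.p[~is_at_class].sum() > 0:
        raise ValueError("spectrum requires G/C sites but genome has none")

    gene_ids = np.array([g.gene_id for g in genes])
    records: list[MutationRecord] = []
    fate_rows = []
    for lin in range(config.n_lineages):
        lineage = f"L{lin + 1}"
        used = np.zeros(n_sites, dtype=bool)
        fixed_sites: list[np.ndarray] = []
        fixed_classes: list[np.ndarray] = []
        n_fixed = n_proposed = n_purged = 0
        while n_fixed < config.n_mutations:
            remaining = config.n_mutations - n_fixed
            batch = max(2 * remaining, 1024)
            j = rng.choice(6, size=batch, p=config.spectrum.p)
            u = rng.random(batch)
            at = is_at_class[j]
            site = np.where(
                at,
                at_sites[(u * at_sites.size).astype(np.int64) % max(at_sites.size, 1)],
                gc_sites[(u * gc_sites.size).astype(np.int64) % max(gc_sites.size, 1)],
            )
            alt = target_lut[j, base[site]]
            syn = syn_lut[codon_idx[site], pos_in_codon[site], alt]
            p_purge = np.where(syn, 0.0, config.selection_nonsyn * q_gene[site_gene[site]])
            if c_lut is not None:
                c_vals = c_lut[codon_idx[site], pos_in_codon[site], alt]
                p_syn_purge = np.minimum(
                    1.0, config.selection_syn * config.syn_selection_scale * np.maximum(0.0, -c_vals)
                )
                p_purge = np.where(syn, p_syn_purge, p_purge)
            purge = rng.random(batch) < p_purge

            # sequential semantics, vectorized: a site fixes at its first
            # fixing occurrence; any later proposal at that site is skipped
            not_used = ~used[site]
            fix_cand = not_used & ~purge
            first_pos = np.full(n_sites, batch, dtype=np.int64)
            cand_pos = np.flatnonzero(fix_cand)
            if cand_pos.size:
                uniq, first = np.unique(site[cand_pos], return_index=True)
                first_pos[uniq] = cand_pos[first]
            idx = np.arange(batch)
            skip = (~not_used) | (idx > first_pos[site])
            proposed = ~skip
            fixed_mask = proposed & ~purge

            cum = np.cumsum(fixed_mask)
            if cum[-1] >= remaining:
                cutoff = int(np.flatnonzero(cum == remaining)[0])
            else:
                cutoff = batch - 1
            window = slice(0, cutoff + 1)
            proposed_w = proposed[window]
            fixed_w = fixed_mask[window]
            n_proposed += int(proposed_w.sum())
            n_purged += int((proposed_w & purge[window]).sum())
            new_sites = site[window][fixed_w]
            used[new_sites] = True
            fixed_sites.append(new_sites)
            fixed_classes.append(j[window][fixed_w])
            n_fixed += int(fixed_w.sum())

        sites = np.concatenate(fixed_sites)
        classes = np.concatenate(fixed_classes)
        quality = rng.uniform(150.0, 400.0, sites.size)
        alt_freq = rng.uniform(0.93, 1.0, sites.size)
        syn_flag = syn_lut[codon_idx[sites], pos_in_codon[sites], target_lut[classes, base[sites]]]
        for i in range(sites.size):
            s = sites[i]
            records.append(
                MutationRecord(
                    gene_id=str(gene_ids[site_gene[s]]),
                    cds_pos=int(offset[s]) + 1,
                    ref=BASES[base[s]],
                    alt=BASES[target_lut[classes[i], base[s]]],
                    lineage=lineage,
                    quality=float(quality[i]),
                    alt_freq=float(alt_freq[i]),
                    annotation="synonymous" if syn_flag[i] else "nonsynonymous",
                )
            )
        fate_rows.append(
            {"lineage": lineage, "proposed": n_proposed, "purged": n_purged, "fixed": n_fixed}
        )

    freqs = np.vstack([g.codon_freq for g in genes])
    p_s = prob_synonymous_many(freqs, config.spectrum, code)
    opportunity = pd.DataFrame(
        {"L": [g.L for g in genes], "P_S": p_s}, index=[g.gene_id for g in genes]
    )
    from .io_formats import mutations_to_frame

    truth = SimulationTruth(
        config=config,
        expression=expression,
        opportunity=opportunity,
        fates=pd.DataFrame(fate_rows),
        mutations=mutations_to_frame(records),
    )
    return records, truth


def simulate(
    config: SimulationConfig, code: GeneticCode = STANDARD_BACTERIAL_CODE
) -> tuple[list[GeneModel], pd.DataFrame, pd.DataFrame, list[MutationRecord], SimulationTruth]:
    """Full experiment: genome + expression + confounders + mutation table.

    The expression summary used for selection is the per-gene mean of the
    quantile-normalized sample matrix, the same path the analysis uses.
    """
    rng = np.random.default_rng(config.seed)
    genes, expr_matrix, confounders = generate_genome(config, code, rng)
    summary = quantile_normalize(expr_matrix).mean(axis=1)
    records, truth = simulate_evolution(genes, summary, config, code, rng)
    return genes, expr_matrix, confounders, records, truth
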