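"""Independent brute-force oracles used to freeze expected values.

These deliberately avoid the package's codon-frequency machinery: they
enumerate every single-base change of the full CDS directly.
"""

import numpy as np

from codonsel.codon_model import (
    BASES,
    SUBSTITUTION_CLASSES,
    GeneModel,
    GeneticCode,
    MutationalSpectrum,
    classify_substitution,
)


def brute_force_prob_synonymous(
    gene: GeneModel, spectrum: MutationalSpectrum, code: GeneticCode
) -> float:
    """Enumerate all L×3 single-base changes, group by class, weight by spectrum."""
    tot = np.zeros(6)
    syn = np.zeros(6)
    index = {c.label: i for i, c in enumerate(SUBSTITUTION_CLASSES)}
    for pos in range(gene.L):
        ref = gene.cds[pos]
        ci = pos // 3
        codon = gene.cds[3 * ci : 3 * ci + 3]
        off = pos % 3
        for alt in BASES:
            if alt == ref:
                continue
            j = index[classify_substitution(ref, alt).label]
            tot[j] += 1
            mutant = codon[:off] + alt + codon[off + 1 :]
            if (not code.is_stop(mutant)) and code.translate(mutant) == code.translate(codon):
                syn[j] += 1
    out = 0.0
    for j in range(6):
        if tot[j] > 0:
            out += spectrum.p[j] * syn[j] / tot[j]
    return out


def exhaustive_synonymous_neighbors(codon: str, code: GeneticCode) -> list[str]:
    out = []
    for i in range(3):
        for b in BASES:
            if b != codon[i]:
                m = codon[:i] + b + codon[i + 1 :]
                if (not code.is_stop(m)) and code.translate(m) == code.translate(codon):
                    out.append(m)
    return out
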