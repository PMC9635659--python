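"""Genetic code, the six-class substitution taxonomy, and codon-level probabilities.

Single-base substitutions on double-stranded DNA come in strand-symmetric
pairs (an A→G on one strand is a T→C on the other), so the 12 ordered base
changes collapse into 6 substitution classes.  A mutational spectrum is a
probability distribution over these classes.  Given a gene's codon usage and
a spectrum, this module computes the probability ``P_S`` that a random
substitution landing in the gene is synonymous — the quantity every
downstream normalization (dN/dS opportunity sites, G-score expectations)
rests on.

All computations interpret mutations against the *ancestral* codon; codon
frequencies are taken from the ancestral sequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "BASES",
    "CODONS",
    "CODON_INDEX",
    "SubstitutionClass",
    "SUBSTITUTION_CLASSES",
    "CLASS_INDEX",
    "GeneticCode",
    "MutationalSpectrum",
    "GeneModel",
    "CodonDistribution",
    "classify_substitution",
    "count_mutant_triplets",
    "count_synonymous_triplets",
    "codon_given_substitution",
    "prob_synonymous",
    "estimate_spectrum",
]

BASES = "ACGT"
#: the 64 codons in alphabetical order; fixed order for serialized vectors
CODONS: tuple[str, ...] = tuple("".join(c) for c in itertools.product(BASES, repeat=3))
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class SubstitutionClass:
    """One of the 6 strand-symmetric substitution classes.

    ``changes`` holds the two complementary ordered base changes the class
    covers, e.g. AT→GC = {A→G, T→C}.  ``source_pair`` is the base pair the
    class mutates away from ("AT" or "GC").
    """

    label: str
    changes: tuple[tuple[str, str], tuple[str, str]]

    @property
    def source_pair(self) -> str:
        return "AT" if self.changes[0][0] in "AT" else "GC"

    def target_of(self, ref: str) -> str:
        """The base that ``ref`` mutates to under this class."""
        for r, a in self.changes:
            if r == ref:
                return a
        raise ValueError(f"base {ref!r} is not mutated by class {self.label}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


#: fixed class order used for all serialized spectra
SUBSTITUTION_CLASSES: tuple[SubstitutionClass, ...] = (
    SubstitutionClass("AT→TA", (("A", "T"), ("T", "A"))),
    SubstitutionClass("GC→CG", (("G", "C"), ("C", "G"))),
    SubstitutionClass("AT→GC", (("A", "G"), ("T", "C"))),
    SubstitutionClass("AT→CG", (("A", "C"), ("T", "G"))),
    SubstitutionClass("GC→AT", (("G", "A"), ("C", "T"))),
    SubstitutionClass("GC→TA", (("G", "T"), ("C", "A"))),
)
CLASS_INDEX: dict[str, int] = {c.label: i for i, c in enumerate(SUBSTITUTION_CLASSES)}

_CHANGE_TO_CLASS: dict[tuple[str, str], SubstitutionClass] = {
    change: cls for cls in SUBSTITUTION_CLASSES for change in cls.changes
}


def classify_substitution(ref: str, alt: str) -> SubstitutionClass:
    """Map an ordered base change to its strand-symmetric class.

    A change and its reverse complement land in the same class, so the 12
    ordered changes partition into the 6 classes exactly.
    """
    ref, alt = str(ref).upper(), str(alt).upper()
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"bases must be one of A/C/G/T, got {ref!r}→{alt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref!r}); not a substitution")
    return _CHANGE_TO_CLASS[(ref, alt)]


class GeneticCode:
    """A codon→amino-acid table; stop codons are mapped to ``'*'``."""

    def __init__(self, table: Mapping[str, str], name: str = "custom"):
        if set(table) != set(CODONS):
            raise ValueError("genetic code must cover exactly the 64 codons")
        self.table: dict[str, str] = dict(table)
        self.name = name
        self.stop_codons = frozenset(c for c, aa in self.table.items() if aa == "*")
        # integer-indexed view used by vectorized helpers
        self._aa = np.array([self.table[c] for c in CODONS])

    @classmethod
    def from_ncbi_id(cls, table_id: int = 11) -> "GeneticCode":
        """Build from an NCBI translation table id (11 = bacterial)."""
        bio = CodonTable.unambiguous_dna_by_id[table_id]
        table = dict(bio.forward_table)
        for stop in bio.stop_codons:
            table[stop] = "*"
        return cls(table, name=f"ncbi-{table_id}")

    def translate(self, codon: str) -> str:
        return self.table[codon.upper()]

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stop_codons

    def synonymous_family(self, codon: str) -> tuple[str, ...]:
        """All sense codons encoding the same amino acid as ``codon``."""
        aa = self.translate(codon)
        if aa == "*":
            raise ValueError(f"{codon} is a stop codon")
        return tuple(c for c in CODONS if self.table[c] == aa)


STANDARD_BACTERIAL_CODE = GeneticCode.from_ncbi_id(11)


@dataclass(frozen=True)
class MutationalSpectrum:
    """Probabilities over the 6 substitution classes, in the fixed class order."""

    p: np.ndarray
    source: str = "unspecified"

    def __post_init__(self):
        arr = np.asarray(self.p, dtype=float)
        if arr.shape != (6,):
            raise ValueError("spectrum must have exactly 6 entries")
        if (arr < 0).any():
            raise ValueError("spectrum entries must be non-negative")
        if abs(arr.sum() - 1.0) > 1e-12:
            raise ValueError(f"spectrum must sum to 1 (got {arr.sum():.15f})")
        object.__setattr__(self, "p", arr)

    @classmethod
    def uniform(cls) -> "MutationalSpectrum":
        return cls(np.full(6, 1 / 6), source="uniform")

    @classmethod
    def from_dict(cls, d: Mapping[str, float], source: str = "dict") -> "MutationalSpectrum":
        return cls(np.array([d.get(c.label, 0.0) for c in SUBSTITUTION_CLASSES], float), source)

    def prob_of(self, cls_or_label) -> float:
        label = getattr(cls_or_label, "label", cls_or_label)
        return float(self.p[CLASS_INDEX[label]])

    def as_dict(self) -> dict[str, float]:
        return {c.label: float(v) for c, v in zip(SUBSTITUTION_CLASSES, self.p)}


class GeneValidationError(ValueError):
    """Raised when a CDS violates frame, alphabet, or internal-stop constraints."""


@dataclass
class GeneModel:
    """One ancestral coding sequence with its codon-usage vector.

    ``codon_freq`` is the relative frequency of each of the 64 codons in
    the gene, in alphabetical codon order; ``L`` is the CDS length in
    nucleotides (a trailing stop codon, if present on input, is trimmed).
    """

    gene_id: str
    cds: str
    L: int = field(init=False)
    codon_freq: np.ndarray = field(init=False)

    def __post_init__(self):
        self.cds = self.cds.upper()
        self.L = len(self.cds)
        counts = np.zeros(64)
        for codon in self.codons():
            counts[CODON_INDEX[codon]] += 1
        self.codon_freq = counts / counts.sum()

    @classmethod
    def from_cds(
        cls,
        gene_id: str,
        cds: str,
        code: GeneticCode = STANDARD_BACTERIAL_CODE,
        trim_trailing_stop: bool = True,
    ) -> "GeneModel":
        seq = str(cds).upper().replace("U", "T")
        if not seq:
            raise GeneValidationError(f"{gene_id}: empty sequence")
        if set(seq) - set(BASES):
            bad = sorted(set(seq) - set(BASES))
            raise GeneValidationError(f"{gene_id}: non-ACGT characters {bad}")
        if len(seq) % 3:
            raise GeneValidationError(f"{gene_id}: length {len(seq)} not a multiple of 3")
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if trim_trailing_stop and code.is_stop(codons[-1]):
            codons = codons[:-1]
            seq = "".join(codons)
            if not codons:
                raise GeneValidationError(f"{gene_id}: sequence is a lone stop codon")
        internal_stops = [i for i, c in enumerate(codons) if code.is_stop(c)]
        if internal_stops:
            raise GeneValidationError(
                f"{gene_id}: internal stop codon(s) at codon position(s) {internal_stops}"
            )
        return cls(gene_id=gene_id, cds=seq)

    def codons(self) -> list[str]:
        return [self.cds[i : i + 3] for i in range(0, self.L, 3)]

    @property
    def n_codons(self) -> int:
        return self.L // 3

    def codon_at(self, cds_pos: int) -> tuple[str, int]:
        """Codon containing 1-based CDS position, and the 0-based offset within it."""
        if not 1 <= cds_pos <= self.L:
            raise ValueError(f"{self.gene_id}: position {cds_pos} outside CDS of length {self.L}")
        i = (cds_pos - 1) // 3
        return self.cds[3 * i : 3 * i + 3], (cds_pos - 1) % 3


def count_mutant_triplets(codon: str, sub_class: SubstitutionClass) -> int:
    """n(sub|cod): number of mutant triplets a class can produce from a codon.

    Each codon position whose base belongs to the class's source pair yields
    exactly one mutant triplet (the class fixes the target base).
    """
    codon = codon.upper()
    if len(codon) != 3 or set(codon) - set(BASES):
        raise ValueError(f"invalid codon {codon!r}")
    return sum(1 for b in codon if b in sub_class.source_pair)


def count_synonymous_triplets(
    codon: str, sub_class: SubstitutionClass, code: GeneticCode = STANDARD_BACTERIAL_CODE
) -> int:
    """n(S|sub∩cod): how many of a class's mutant triplets are synonymous.

    Stop-gaining changes count as nonsynonymous; stop codons are rejected as
    input because the ancestral CDS must be coding.
    """
    codon = codon.upper()
    if len(codon) != 3 or set(codon) - set(BASES):
        raise ValueError(f"invalid codon {codon!r}")
    if code.is_stop(codon):
        raise ValueError(f"{codon} is a stop codon; ancestral codons must be sense codons")
    aa = code.translate(codon)
    n = 0
    for i, b in enumerate(codon):
        if b in sub_class.source_pair:
            mutant = codon[:i] + sub_class.target_of(b) + codon[i + 1 :]
            if code.translate(mutant) == aa:
                n += 1
    return n


def _opportunity_matrices(code: GeneticCode) -> tuple[np.ndarray, np.ndarray]:
    """(64×6) matrices of n(sub|cod) and n(S|sub∩cod); n(S|·)=0 at stop codons."""
    n_mut = np.zeros((64, 6))
    n_syn = np.zeros((64, 6))
    for k, codon in enumerate(CODONS):
        for j, cls in enumerate(SUBSTITUTION_CLASSES):
            n_mut[k, j] = count_mutant_triplets(codon, cls)
            if not code.is_stop(codon):
                n_syn[k, j] = count_synonymous_triplets(codon, cls, code)
    return n_mut, n_syn


_MATRIX_CACHE: dict[str, tuple[np.ndarray, np.ndarray]] = {}


def opportunity_matrices(code: GeneticCode = STANDARD_BACTERIAL_CODE):
    if code.name not in _MATRIX_CACHE:
        _MATRIX_CACHE[code.name] = _opportunity_matrices(code)
    return _MATRIX_CACHE[code.name]


@dataclass(frozen=True)
class CodonDistribution:
    """P(cod|sub) over the 64 codons; ``degenerate`` marks zero total opportunity."""

    probs: np.ndarray
    degenerate: bool

    def as_dict(self) -> dict[str, float]:
        return {c: float(p) for c, p in zip(CODONS, self.probs) if p > 0}


def codon_given_substitution(gene: GeneModel, sub_class: SubstitutionClass) -> CodonDistribution:
    """P(cod_k|sub_j): which codon a class-j substitution in the gene hits.

    Weights each codon's usage by its class-j opportunity and renormalizes.
    If the gene carries no base of the class's source pair the result is
    flagged degenerate (all-zero probabilities) rather than raising.
    """
    n_mut, _ = opportunity_matrices()
    j = CLASS_INDEX[sub_class.label]
    weights = gene.codon_freq * n_mut[:, j]
    total = weights.sum()
    if total <= 0:
        return CodonDistribution(np.zeros(64), degenerate=True)
    return CodonDistribution(weights / total, degenerate=False)


def prob_synonymous(
    gene: GeneModel,
    spectrum: MutationalSpectrum,
    code: GeneticCode = STANDARD_BACTERIAL_CODE,
    renormalize_infeasible: bool = False,
) -> float:
    """P_S: probability that a substitution in the gene is synonymous.

    P_S = Σ_j P(sub_j) Σ_k P(cod_k|sub_j) · n(S|sub_j∩cod_k)/n(sub_j|cod_k),
    which reduces to the spectrum-weighted fraction of synonymous class-j
    events among all class-j events offered by the gene's codon usage.

    Classes with zero opportunity in the gene contribute 0; by default the
    spectrum is *not* renormalized over the feasible classes (the formula
    taken literally).  ``renormalize_infeasible=True`` switches to
    renormalization over classes with nonzero opportunity.
    """
    n_mut, n_syn = opportunity_matrices(code)
    tot = gene.codon_freq @ n_mut  # per-class event mass, shape (6,)
    syn = gene.codon_freq @ n_syn
    feasible = tot > 0
    if not feasible.any():
        raise ValueError(f"{gene.gene_id}: no possible substitution in gene")
    frac = np.zeros(6)
    frac[feasible] = syn[feasible] / tot[feasible]
    p_s = float(spectrum.p @ frac)
    if renormalize_infeasible:
        mass = spectrum.p[feasible].sum()
        if mass <= 0:
            raise ValueError("spectrum has zero mass on feasible classes")
        p_s = float(spectrum.p[feasible] @ frac[feasible] / mass)
    return p_s


def prob_synonymous_many(
    codon_freqs: np.ndarray,
    spectrum: MutationalSpectrum,
    code: GeneticCode = STANDARD_BACTERIAL_CODE,
) -> np.ndarray:
    """Vectorized P_S for a (genes × 64) codon-frequency matrix."""
    n_mut, n_syn = opportunity_matrices(code)
    tot = codon_freqs @ n_mut
    syn = codon_freqs @ n_syn
    frac = np.divide(syn, tot, out=np.zeros_like(syn), where=tot > 0)
    return frac @ spectrum.p


def estimate_spectrum(mutations: Iterable) -> MutationalSpectrum:
    """Estimate the spectrum from observed (synonymous) substitutions.

    Counts over the 6 classes, normalized to sum to 1.  Accepts any objects
    with ``ref``/``alt`` attributes, or (ref, alt) pairs.
    """
    counts = np.zeros(6)
    n = 0
    for rec in mutations:
        ref = getattr(rec, "ref", None)
        alt = getattr(rec, "alt", None)
        if ref is None:
            ref, alt = rec
        counts[CLASS_INDEX[classify_substitution(ref, alt).label]] += 1
        n += 1
    if n == 0:
        raise ValueError(
            "no substitutions to estimate a spectrum from; "
            "consider MutationalSpectrum.uniform() as a fallback"
        )
    return MutationalSpectrum(counts / counts.sum(), source=f"estimated from {n} substitutions")
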