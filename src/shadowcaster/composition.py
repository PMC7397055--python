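"""Per-gene compositional features against the whole-genome background.

Two classic genomic-signature features are computed for every gene:

* a chi-square statistic over overlapping tetranucleotide (4-mer)
  frequencies, gene versus the concatenated coding sequence of the genome;
* the Kullback-Leibler divergence (nats, gene || genome) of codon usage
  over the 61 sense codons.

Frequencies are pseudocounted so every background frequency is strictly
positive; windows or codons containing N are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np

from .genome_io import GeneRecord, STOP_CODONS

_BASES = "ACGT"
_LUT = np.full(256, -2, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _LUT[ord(_b)] = _i
_LUT[ord("N")] = -1

#: the 61 sense codons of the bacterial genetic code, lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in product(_BASES, repeat=3) if "".join(c) not in STOP_CODONS
)
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}


def kmer_words(k: int = 4) -> list[str]:
    """All 4^k DNA words in lexicographic order (the profile's support)."""
    return ["".join(w) for w in product(_BASES, repeat=k)]


@dataclass(frozen=True)
class KmerProfile:
    """Counts and pseudocounted frequencies over all 4^k DNA k-mers."""

    counts: np.ndarray
    n_windows: int
    k: int = 4
    pseudocount: float = 1.0

    @property
    def freqs(self) -> np.ndarray:
        denom = self.n_windows + self.pseudocount * len(self.counts)
        return (self.counts + self.pseudocount) / denom


@dataclass(frozen=True)
class CodonProfile:
    """Counts and pseudocounted frequencies over the 61 sense codons."""

    counts: np.ndarray
    n_codons: int
    pseudocount: float = 1.0

    @property
    def freqs(self) -> np.ndarray:
        denom = self.n_codons + self.pseudocount * len(self.counts)
        return (self.counts + self.pseudocount) / denom


@dataclass(frozen=True)
class FeatureVector:
    gene_id: str
    chi2_4mer: float
    kl_codon: float


def _kmer_counts(seq: str, k: int) -> tuple[np.ndarray, int]:
    codes = _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == -2).any():
        raise ValueError("sequence contains non-DNA characters")
    if len(codes) < k:
        raise ValueError(f"sequence shorter than k={k}")
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1)
    idx = windows[valid] @ powers
    counts = np.bincount(idx, minlength=4**k)
    return counts, int(valid.sum())


def kmer_profile(seq: str, k: int = 4, pseudocount: float = 1.0) -> KmerProfile:
    """Overlapping k-mer profile of one sequence (step 1, N-windows skipped)."""
    counts, n_windows = _kmer_counts(seq.upper(), k)
    return KmerProfile(counts=counts, n_windows=n_windows, k=k, pseudocount=pseudocount)


def _codon_counts(gene: GeneRecord) -> tuple[np.ndarray, int]:
    counts = np.zeros(len(SENSE_CODONS), dtype=np.int64)
    nt = gene.nt_seq
    n = 0
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        j = _CODON_INDEX.get(codon)
        if j is None:  # stop codon or codon containing N
            continue
        counts[j] += 1
        n += 1
    return counts, n


def codon_profile(gene: GeneRecord, pseudocount: float = 1.0) -> CodonProfile:
    """Sense-codon usage of one CDS (trailing stop and N-codons skipped)."""
    counts, n = _codon_counts(gene)
    if n == 0:
        raise ValueError(f"gene {gene.gene_id!r} has no countable sense codons")
    return CodonProfile(counts=counts, n_codons=n, pseudocount=pseudocount)


def genome_profile(
    genes: Sequence[GeneRecord], k: int = 4, pseudocount: float = 1.0
) -> tuple[KmerProfile, CodonProfile]:
    """Background profiles over the concatenated coding sequence.

    Genes are counted separately and the counts pooled, so no window spans
    a gene boundary.
    """
    if not genes:
        raise ValueError("empty gene list")
    kmer_counts = np.zeros(4**k, dtype=np.int64)
    n_windows = 0
    codon_counts = np.zeros(len(SENSE_CODONS), dtype=np.int64)
    n_codons = 0
    for g in genes:
        c, w = _kmer_counts(g.nt_seq, k)
        kmer_counts += c
        n_windows += w
        cc, nc = _codon_counts(g)
        codon_counts += cc
        n_codons += nc
    return (
        KmerProfile(counts=kmer_counts, n_windows=n_windows, k=k, pseudocount=pseudocount),
        CodonProfile(counts=codon_counts, n_codons=n_codons, pseudocount=pseudocount),
    )


def chi2_feature(gene: KmerProfile, genome: KmerProfile) -> float:
    """Chi-square distance sum_w (f_gene - f_genome)^2 / f_genome."""
    if gene.k != genome.k or len(gene.counts) != len(genome.counts):
        raise ValueError("k-mer profiles are over different alphabets")
    fg, fG = gene.freqs, genome.freqs
    return float(np.sum((fg - fG) ** 2 / fG))


def kl_feature(gene: CodonProfile, genome: CodonProfile) -> float:
    """Kullback-Leibler divergence sum_c p ln(p/q), gene || genome, in nats."""
    if len(gene.counts) != len(genome.counts):
        raise ValueError("codon profiles are over different supports")
    p, q = gene.freqs, genome.freqs
    return float(np.sum(p * np.log(p / q)))


def feature_table(
    genes: Sequence[GeneRecord], k: int = 4, pseudocount: float = 1.0
) -> list[FeatureVector]:
    """One (chi2_4mer, kl_codon) pair per gene, against the pooled genome."""
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to define a genome background")
    genome_kmer, genome_codon = genome_profile(genes, k=k, pseudocount=pseudocount)
    out: list[FeatureVector] = []
    for g in genes:
        try:
            fv = FeatureVector(
                gene_id=g.gene_id,
                chi2_4mer=chi2_feature(kmer_profile(g.nt_seq, k, pseudocount), genome_kmer),
                kl_codon=kl_feature(codon_profile(g, pseudocount), genome_codon),
            )
        except ValueError as exc:
            raise ValueError(f"gene {g.gene_id!r}: {exc}") from exc
        out.append(fv)
    return out


def write_feature_table(features: Sequence[FeatureVector], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchi2_4mer\tkl_codon\n")
        for f in features:
            fh.write(f"{f.gene_id}\t{f.chi2_4mer:.6f}\t{f.kl_codon:.6f}\n")
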