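"""Construction of the phylogenetic shadow.

The shadow is a weighted set of proteomes at graded taxonomic distances
from the query species (40% same family, 20% same order, 20% same phylum,
12% same superkingdom, 8% another prokaryotic superkingdom).  For each
selected species, reciprocal-best-hit (RBH) orthologs against the query
proteome yield

* ``p0`` — the shared-orthology probability (orthologs / query proteome
  size), the prior proxy for phylogenetic proximity, and
* a Gaussian vertical-inheritance model (mean, std of ortholog percent
  identities from global alignments).

Percent identity everywhere is matches / alignment length (gaps included)
from a Needleman-Wunsch global alignment with BLOSUM62, gap open 10,
gap extend 0.5 — the EMBOSS ``needle`` convention.  Because a full
BLOSUM62 all-vs-all is quadratic and slow, best-hit *candidates* are
screened first by amino-acid 2-mer composition and ranked by unit-cost
global edit distance (edlib); the identity of every selected pair is then
recomputed with the BLOSUM62 aligner, so all reported and fitted
identities share one scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import floor
from typing import Mapping, Sequence

import edlib
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial.distance import cdist

from .genome_io import Proteome, TaxonomyRecord

logger = logging.getLogger(__name__)

#: taxonomic ranks from most to least specific; promotion cascades rightward
RANKS: tuple[str, ...] = ("family", "order", "phylum", "kingdom", "other_kingdom")

DEFAULT_WEIGHTS: dict[str, float] = {
    "family": 0.40,
    "order": 0.20,
    "phylum": 0.20,
    "kingdom": 0.12,
    "other_kingdom": 0.08,
}


@dataclass(frozen=True)
class ShadowSpec:
    """Requested shadow size and per-rank taxonomic weights."""

    total: int = 25
    weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))

    def __post_init__(self) -> None:
        if self.total < 5:
            raise ValueError(f"shadow total must be >= 5, got {self.total}")
        if set(self.weights) != set(RANKS):
            raise ValueError(f"weights must cover exactly the ranks {RANKS}")
        if abs(sum(self.weights.values()) - 1.0) > 1e-12:
            raise ValueError("rank weights must sum to 1.0 exactly")


@dataclass
class ShadowSpecies:
    """One shadow proteome with its fitted vertical-inheritance model."""

    species_id: str
    rank_matched: str
    proteome: Proteome
    n_orthologs: int = 0
    p0: float | None = None
    mu_identity: float | None = None
    sigma_identity: float | None = None
    informative: bool = False


@dataclass(frozen=True)
class OrthologPair:
    query_protein_id: str
    subject_protein_id: str
    identity_pct: float


def allocate_counts(spec: ShadowSpec, available: Mapping[str, int]) -> dict[str, int]:
    """Per-rank species counts: largest-remainder rounding + deficit promotion.

    Ideal counts are total x weight rounded by largest remainder so they sum
    to the requested total.  A rank's shortfall against its candidate pool is
    promoted to the next more-inclusive rank and cascades; a shortfall left
    at the most inclusive rank reduces the achieved total with a warning.
    """
    ideal = {r: spec.total * spec.weights[r] for r in RANKS}
    base = {r: floor(ideal[r]) for r in RANKS}
    short = spec.total - sum(base.values())
    # ties in remainder broken toward the more specific rank
    by_remainder = sorted(RANKS, key=lambda r: (-(ideal[r] - base[r]), RANKS.index(r)))
    for r in by_remainder[:short]:
        base[r] += 1

    taken: dict[str, int] = {}
    carry = 0
    for r in RANKS:
        want = base[r] + carry
        avail = int(available.get(r, 0))
        taken[r] = min(want, avail)
        carry = want - taken[r]
    achieved = sum(taken.values())
    if achieved == 0:
        raise ValueError(
            f"candidate pool empty: achieved 0 of the requested {spec.total} shadow species"
        )
    if carry > 0:
        logger.warning(
            "shadow pool short at the most inclusive rank: achieved %d of %d",
            achieved,
            spec.total,
        )
    return taken


def bucket_rank(query: TaxonomyRecord, candidate: TaxonomyRecord) -> str:
    """Most specific rank at which a candidate matches the query taxonomy.

    ``NA`` labels never match; a different superkingdom is ``other_kingdom``.
    """
    if candidate.superkingdom != query.superkingdom:
        return "other_kingdom"
    if candidate.family != "NA" and candidate.family == query.family:
        return "family"
    if candidate.order != "NA" and candidate.order == query.order:
        return "order"
    if candidate.phylum != "NA" and candidate.phylum == query.phylum:
        return "phylum"
    return "kingdom"


def select_shadow(
    query_tax: TaxonomyRecord,
    pool: Sequence[tuple[TaxonomyRecord, Proteome]],
    spec: ShadowSpec = ShadowSpec(),
    seed: int = 0,
) -> list[ShadowSpecies]:
    """Sample the shadow species from the candidate pool by taxonomic weight."""
    if not pool:
        raise ValueError("candidate pool is empty")
    buckets: dict[str, list[tuple[TaxonomyRecord, Proteome]]] = {r: [] for r in RANKS}
    for tax, prot in pool:
        if tax.species_id == query_tax.species_id:
            raise ValueError(f"query species {tax.species_id!r} present in the pool")
        buckets[bucket_rank(query_tax, tax)].append((tax, prot))
    for r in RANKS:
        buckets[r].sort(key=lambda tp: tp[0].species_id)

    counts = allocate_counts(spec, {r: len(buckets[r]) for r in RANKS})
    rng = np.random.default_rng(seed)
    selected: list[ShadowSpecies] = []
    for r in RANKS:
        if counts[r] == 0:
            continue
        idx = rng.choice(len(buckets[r]), size=counts[r], replace=False)
        for i in sorted(idx):
            tax, prot = buckets[r][i]
            selected.append(ShadowSpecies(species_id=tax.species_id, rank_matched=r, proteome=prot))
    if not selected:
        raise ValueError("no shadow species could be selected")
    return selected


_ALIGNER: Align.PairwiseAligner | None = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        a = Align.PairwiseAligner()
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -10.0
        a.extend_gap_score = -0.5
        a.mode = "global"
        _ALIGNER = a
    return _ALIGNER


def global_identity(a: str, b: str) -> float:
    """Percent identity of the global BLOSUM62 alignment of two proteins.

    Identity = 100 x matches / alignment length, gaps counted in the
    denominator.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aln = _aligner().align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(x == y for x, y in zip(s1, s2))
    return 100.0 * matches / len(s1)


def _aa_kmer_freqs(seqs: Sequence[str], k: int = 2) -> np.ndarray:
    """Amino-acid k-mer frequency matrix used as a cheap candidate screen."""
    lut = np.full(256, -1, dtype=np.int64)
    for i, c in enumerate("ACDEFGHIKLMNPQRSTVWYX"):
        lut[ord(c)] = i
    n_sym = 21
    out = np.zeros((len(seqs), n_sym**k))
    for row, s in enumerate(seqs):
        codes = lut[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
        if len(codes) < k:
            continue
        win = np.lib.stride_tricks.sliding_window_view(codes, k)
        idx = win @ (n_sym ** np.arange(k - 1, -1, -1))
        counts = np.bincount(idx, minlength=n_sym**k)
        out[row] = counts / max(len(codes) - k + 1, 1)
    return out


def _candidate_lists(
    query_seqs: Sequence[str], subject_seqs: Sequence[str], n_candidates: int
) -> np.ndarray:
    """Top candidate subject indices per query by 2-mer composition distance."""
    nq, ns = len(query_seqs), len(subject_seqs)
    if ns <= n_candidates:
        return np.tile(np.arange(ns), (nq, 1))
    d = cdist(_aa_kmer_freqs(query_seqs), _aa_kmer_freqs(subject_seqs), metric="euclidean")
    # penalize large length differences, which bound the edit distance below
    ql = np.array([len(s) for s in query_seqs], dtype=float)
    sl = np.array([len(s) for s in subject_seqs], dtype=float)
    d += 1e-4 * np.abs(ql[:, None] - sl[None, :])
    part = np.argpartition(d, n_candidates - 1, axis=1)[:, :n_candidates]
    return part


def _best_hits(
    query_seqs: Sequence[str],
    subject_seqs: Sequence[str],
    subject_ids: Sequence[str],
    n_candidates: int = 10,
) -> np.ndarray:
    """Best subject index per query by global edit distance over candidates.

    Ties in edit distance are broken by lexicographic subject protein id.
    """
    cand = _candidate_lists(query_seqs, subject_seqs, n_candidates)
    best = np.empty(len(query_seqs), dtype=np.int64)
    for qi, q in enumerate(query_seqs):
        best_d = 10**9
        best_j = -1
        row = cand[qi]
        # try length-closest candidates first: tighter pruning bound sooner
        row = row[np.argsort([abs(len(subject_seqs[j]) - len(q)) for j in row])]
        hits: list[tuple[int, int]] = []
        for j in row:
            s = subject_seqs[j]
            if abs(len(s) - len(q)) > best_d:
                continue
            res = edlib.align(q, s, mode="NW", task="distance", k=best_d)
            dist = res["editDistance"]
            if dist == -1:
                continue
            if dist < best_d:
                best_d, best_j = dist, j
                hits = [(dist, j)]
            elif dist == best_d:
                hits.append((dist, j))
        if len(hits) > 1:
            best_j = min(hits, key=lambda h: subject_ids[h[1]])[1]
        best[qi] = best_j
    return best


def rbh_orthologs(
    query: Proteome,
    subject: Proteome,
    min_identity: float = 30.0,
    n_candidates: int = 10,
) -> list[OrthologPair]:
    """Reciprocal-best-hit ortholog pairs between two proteomes.

    A pair is kept iff each protein is the other's best global-alignment
    hit and the BLOSUM62 global identity is >= ``min_identity`` percent.
    """
    if not len(query) or not len(subject):
        raise ValueError("both proteomes must be non-empty")
    q_seqs, q_ids = query.sequences, query.ids
    s_seqs, s_ids = subject.sequences, subject.ids
    fwd = _best_hits(q_seqs, s_seqs, s_ids, n_candidates)
    rev = _best_hits(s_seqs, q_seqs, q_ids, n_candidates)
    pairs: list[OrthologPair] = []
    for qi, sj in enumerate(fwd):
        if sj >= 0 and rev[sj] == qi:
            ident = global_identity(q_seqs[qi], s_seqs[sj])
            if ident >= min_identity:
                pairs.append(OrthologPair(q_ids[qi], s_ids[sj], ident))
    return pairs


@dataclass(frozen=True)
class VerticalModel:
    mu_identity: float | None
    sigma_identity: float | None
    n_orthologs: int
    p0: float
    informative: bool


def fit_vertical_model(
    pairs: Sequence[OrthologPair],
    query_size: int,
    sigma_floor: float = 1.0,
    p0_floor: float = 1e-4,
) -> VerticalModel:
    """Gaussian vertical-inheritance model and prior for one shadow species.

    ``p0`` is orthologs over the query proteome size, floored so its log is
    finite; the identity std is floored so the density is proper.  With zero
    pairs the species is uninformative and excluded from likelihood sums.
    """
    if query_size <= 0:
        raise ValueError("query proteome size must be positive")
    n = len(pairs)
    p0 = max(n / query_size, p0_floor)
    if n == 0:
        return VerticalModel(None, None, 0, p0, informative=False)
    ids = np.array([p.identity_pct for p in pairs], dtype=float)
    mu = float(ids.mean())
    sigma = float(ids.std(ddof=1)) if n > 1 else 0.0
    sigma = max(sigma, sigma_floor)
    return VerticalModel(mu, sigma, n, p0, informative=True)


def fit_shadow(
    query: Proteome,
    species: Sequence[ShadowSpecies],
    min_identity: float = 30.0,
    sigma_floor: float = 1.0,
    p0_floor: float = 1e-4,
    n_candidates: int = 10,
) -> list[ShadowSpecies]:
    """Fit p0 and the identity Gaussian of every shadow species in place."""
    for sp in species:
        pairs = rbh_orthologs(query, sp.proteome, min_identity, n_candidates)
        vm = fit_vertical_model(pairs, len(query), sigma_floor, p0_floor)
        sp.n_orthologs = vm.n_orthologs
        sp.p0 = vm.p0
        sp.mu_identity = vm.mu_identity
        sp.sigma_identity = vm.sigma_identity
        sp.informative = vm.informative
        logger.info(
            "shadow species %s (%s): %d orthologs, p0=%.4f, mu=%s, sigma=%s",
            sp.species_id,
            sp.rank_matched,
            vm.n_orthologs,
            vm.p0,
            f"{vm.mu_identity:.2f}" if vm.informative else "NA",
            f"{vm.sigma_identity:.2f}" if vm.informative else "NA",
        )
    return list(species)


def write_shadow_manifest(species: Sequence[ShadowSpecies], path) -> None:
    with open(path, "w") as fh:
        fh.write("species_id\trank_matched\tn_orthologs\tp0\tmu_identity\tsigma_identity\n")
        for sp in species:
            mu = f"{sp.mu_identity:.4f}" if sp.mu_identity is not None else "NA"
            sd = f"{sp.sigma_identity:.4f}" if sp.sigma_identity is not None else "NA"
            p0 = f"{sp.p0:.6f}" if sp.p0 is not None else "NA"
            fh.write(f"{sp.species_id}\t{sp.rank_matched}\t{sp.n_orthologs}\t{p0}\t{mu}\t{sd}\n")
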