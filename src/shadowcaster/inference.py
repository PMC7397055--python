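"""Vertical-inheritance likelihood of atypical genes and the HGT split.

For each atypical gene, the best global-alignment identity of its protein
in every shadow proteome forms the evidence vector y.  Species whose best
hit exceeds the identity gate (default 55%) and that carry an informative
vertical model contribute

    log N(y_s | mu_s, sigma_s) + ln p0_s

i.e. the log posterior of orthology (sampling density of the identity under
the vertical model, times the shared-orthology prior) up to a constant.
The per-gene log-likelihood is the *mean* of the contributing terms, so a
gene is not penalized merely for having orthologs in many species.  Genes
with no qualifying hit (potential ORFans) carry a NO_EVIDENCE sentinel and
are never called HGT.

The log-likelihoods of all atypical genes are split into two classes with
one-dimensional fuzzy c-means; the lower-likelihood class is the HGT call,
the other the vertically inherited genes of unusual composition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genome_io import GeneRecord
from .shadow import ShadowSpecies, _best_hits, global_identity

logger = logging.getLogger(__name__)

HGT = "HGT"
VERTICAL_ATYPICAL = "VERTICAL_ATYPICAL"
NO_EVIDENCE = "NO_EVIDENCE"
TYPICAL = "TYPICAL"

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class IdentityVector:
    """Best-hit percent identity of one gene's protein in each shadow species."""

    gene_id: str
    hits: Mapping[str, float]
    reason: str | None = None  # "short" when excluded by the length filter


@dataclass(frozen=True)
class GeneLikelihood:
    gene_id: str
    loglik: float | None  # None == NO_EVIDENCE
    n_contributing: int


@dataclass(frozen=True)
class FuzzyPartition:
    centroids: tuple[float, float]  # (low, high)
    memberships: np.ndarray  # shape (n, 2), columns (m_low, m_high)
    degenerate: bool = False


@dataclass(frozen=True)
class HGTCall:
    gene_id: str
    loglik: float | None
    membership_hgt: float | None
    call: str


def identity_vectors(
    genes: Sequence[GeneRecord],
    shadow: Sequence[ShadowSpecies],
    min_len_aa: int = 70,
    n_candidates: int = 10,
) -> list[IdentityVector]:
    """Evidence vectors for a batch of genes (shared per-species screening).

    Genes whose protein is not longer than ``min_len_aa`` are excluded from
    the phylogenetic stage entirely (empty hits, reason ``"short"``).
    """
    if not shadow:
        raise ValueError("empty phylogenetic shadow")
    long_idx = [i for i, g in enumerate(genes) if len(g.aa_seq) > min_len_aa]
    hits_per_gene: list[dict[str, float]] = [dict() for _ in genes]
    if long_idx:
        q_seqs = [genes[i].aa_seq for i in long_idx]
        for sp in shadow:
            s_seqs, s_ids = sp.proteome.sequences, sp.proteome.ids
            best = _best_hits(q_seqs, s_seqs, s_ids, n_candidates)
            for qi, sj in zip(long_idx, best):
                if sj >= 0:
                    hits_per_gene[qi][sp.species_id] = global_identity(
                        genes[qi].aa_seq, s_seqs[sj]
                    )
    return [
        IdentityVector(
            gene_id=g.gene_id,
            hits=hits_per_gene[i],
            reason=None if i in set(long_idx) else "short",
        )
        for i, g in enumerate(genes)
    ]


def best_hit_identities(
    gene: GeneRecord,
    shadow: Sequence[ShadowSpecies],
    min_len_aa: int = 70,
    n_candidates: int = 10,
) -> IdentityVector:
    """Single-gene convenience wrapper around :func:`identity_vectors`."""
    return identity_vectors([gene], shadow, min_len_aa, n_candidates)[0]


def gene_loglikelihood(
    y: IdentityVector,
    shadow: Sequence[ShadowSpecies],
    identity_gate: float = 55.0,
) -> GeneLikelihood:
    """Mean per-species log posterior of vertical inheritance for one gene.

    Only species with a best-hit identity strictly above the gate and an
    informative fitted model contribute; an empty contributing set yields
    the NO_EVIDENCE sentinel (loglik None).
    """
    terms: list[float] = []
    for sp in shadow:
        ident = y.hits.get(sp.species_id)
        if ident is None or ident <= identity_gate or not sp.informative:
            continue
        if sp.sigma_identity is None or sp.sigma_identity <= 0:
            raise ValueError(f"species {sp.species_id!r}: non-positive identity std")
        z = (ident - sp.mu_identity) / sp.sigma_identity
        logpdf = -math.log(sp.sigma_identity) - _LOG_SQRT_2PI - 0.5 * z * z
        terms.append(logpdf + math.log(sp.p0))
    if not terms:
        return GeneLikelihood(gene_id=y.gene_id, loglik=None, n_contributing=0)
    return GeneLikelihood(
        gene_id=y.gene_id,
        loglik=float(np.mean(terms)),
        n_contributing=len(terms),
    )


def fuzzy_two_class(
    logliks: Sequence[float],
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> FuzzyPartition:
    """Fuzzy c-means with c=2 on scalar log-likelihoods.

    Centroids start deterministically at the data minimum and maximum, so
    the run is reproducible.  Identical values (zero spread) yield a
    degenerate partition and no HGT calls downstream.
    """
    x = np.asarray(logliks, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to cluster")
    if not np.all(np.isfinite(x)):
        raise ValueError("log-likelihoods must be finite")
    if x.max() - x.min() == 0:
        u = np.full((x.size, 2), 0.5)
        return FuzzyPartition((float(x[0]), float(x[0])), u, degenerate=True)

    c = np.array([x.min(), x.max()], dtype=float)
    expo = 2.0 / (m - 1.0)
    u = np.empty((x.size, 2))
    for _ in range(max_iter):
        d = np.abs(x[:, None] - c[None, :])
        zero = d < 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d ** (-expo)
            u = inv / inv.sum(axis=1, keepdims=True)
        rows = zero.any(axis=1)
        u[rows] = zero[rows].astype(float)
        w = u**m
        c_new = (w * x[:, None]).sum(axis=0) / w.sum(axis=0)
        shift = np.abs(c_new - c).max()
        c = c_new
        if shift < tol:
            break
    order = np.argsort(c)
    return FuzzyPartition(
        centroids=(float(c[order[0]]), float(c[order[1]])),
        memberships=u[:, order],
        degenerate=bool(abs(c[order[1]] - c[order[0]]) < 1e-12),
    )


def call_hgt(
    partition: FuzzyPartition, likelihoods: Sequence[GeneLikelihood]
) -> list[HGTCall]:
    """Assign HGT / VERTICAL_ATYPICAL / NO_EVIDENCE per atypical gene.

    Partition rows correspond, in order, to the genes with a finite
    log-likelihood.  HGT = membership > 0.5 in the lower-centroid class.
    """
    finite = [gl for gl in likelihoods if gl.loglik is not None]
    if partition.memberships.shape[0] != len(finite):
        raise ValueError("partition size does not match the scored genes")
    if partition.degenerate:
        logger.warning("degenerate fuzzy partition: no HGT calls made")
    calls: list[HGTCall] = []
    it = iter(range(len(finite)))
    for gl in likelihoods:
        if gl.loglik is None:
            calls.append(HGTCall(gl.gene_id, None, None, NO_EVIDENCE))
            continue
        row = next(it)
        m_low = float(partition.memberships[row, 0])
        if partition.degenerate:
            calls.append(HGTCall(gl.gene_id, gl.loglik, m_low, VERTICAL_ATYPICAL))
        else:
            call = HGT if m_low > 0.5 else VERTICAL_ATYPICAL
            calls.append(HGTCall(gl.gene_id, gl.loglik, m_low, call))
    return calls
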