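"""End-to-end orchestration: parametric stage -> shadow -> likelihood calls.

The three stages run strictly in sequence: (i) one-class-SVM atypical-gene
identification from the two compositional features, (ii) phylogenetic-shadow
construction and vertical-model fitting, (iii) per-gene log-likelihood and
the fuzzy two-class split.  Only genes flagged atypical in (i) ever reach
(ii)/(iii); typical genes are carried through to the final table with the
call TYPICAL so detection rates are computable from one file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .composition import FeatureVector, feature_table, write_feature_table
from .genome_io import (
    GeneRecord,
    Proteome,
    TaxonomyRecord,
    read_cds_fasta,
    read_proteome_fasta,
    read_taxonomy_table,
    write_cds_fasta,
)
from .inference import (
    NO_EVIDENCE,
    TYPICAL,
    GeneLikelihood,
    HGTCall,
    IdentityVector,
    call_hgt,
    fuzzy_two_class,
    gene_loglikelihood,
    identity_vectors,
)
from .outlier import AtypicalCall, SvmConfig, fit_predict_atypical, write_atypical_calls
from .shadow import ShadowSpec, ShadowSpecies, fit_shadow, select_shadow, write_shadow_manifest

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "gene_id",
    "chi2_4mer",
    "kl_codon",
    "svm_score",
    "is_atypical",
    "loglik",
    "membership_hgt",
    "call",
]


@dataclass(frozen=True)
class RunConfig:
    """All tunable thresholds of a run, serializable to the manifest."""

    nu: float = 0.4
    n_shadow: int = 25
    identity_gate: float = 55.0
    min_aa: int = 70
    pseudocount: float = 1.0
    min_identity: float = 30.0
    sigma_floor: float = 1.0
    p0_floor: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.nu <= 1:
            raise ValueError("nu must be in (0, 1]")
        if self.n_shadow < 5:
            raise ValueError("n_shadow must be >= 5")
        if not 0 <= self.identity_gate <= 100:
            raise ValueError("identity_gate must be a percentage")
        if self.min_aa < 0 or self.pseudocount <= 0:
            raise ValueError("invalid min_aa or pseudocount")


def fit_shadow_model(
    query_proteome: Proteome,
    pool: Sequence[tuple[TaxonomyRecord, Proteome]],
    query_tax: TaxonomyRecord,
    config: RunConfig = RunConfig(),
) -> list[ShadowSpecies]:
    """Stage (ii): select shadow species and fit p0 + identity Gaussians."""
    selected = select_shadow(query_tax, pool, ShadowSpec(total=config.n_shadow), config.seed)
    return fit_shadow(
        query_proteome,
        selected,
        min_identity=config.min_identity,
        sigma_floor=config.sigma_floor,
        p0_floor=config.p0_floor,
    )


def phylogenetic_stage(
    atypical_genes: Sequence[GeneRecord],
    shadow: Sequence[ShadowSpecies],
    config: RunConfig = RunConfig(),
    precomputed: dict[str, IdentityVector] | None = None,
) -> list[HGTCall]:
    """Stage (iii): likelihoods and the fuzzy HGT / vertical split.

    ``precomputed`` optionally maps gene_id to an IdentityVector (e.g. when
    sweeping nu over a fixed dataset) so alignments are not redone.
    """
    if not atypical_genes:
        return []
    if precomputed is not None:
        ivs = [precomputed[g.gene_id] for g in atypical_genes]
    else:
        ivs = identity_vectors(atypical_genes, shadow, min_len_aa=config.min_aa)
    liks = [gene_loglikelihood(iv, shadow, config.identity_gate) for iv in ivs]
    finite = [gl.loglik for gl in liks if gl.loglik is not None]
    if len(finite) < 2:
        logger.warning("fewer than 2 scored atypical genes: no HGT calls possible")
        return [
            HGTCall(gl.gene_id, gl.loglik, None, NO_EVIDENCE if gl.loglik is None else "VERTICAL_ATYPICAL")
            for gl in liks
        ]
    partition = fuzzy_two_class(finite)
    return call_hgt(partition, liks)


def _results_frame(
    genes: Sequence[GeneRecord],
    features: Sequence[FeatureVector],
    svm_calls: Sequence[AtypicalCall],
    hgt_calls: Sequence[HGTCall],
) -> pd.DataFrame:
    by_id = {c.gene_id: c for c in hgt_calls}
    rows = []
    for g, f, s in zip(genes, features, svm_calls):
        if not s.is_atypical:
            rows.append((g.gene_id, f.chi2_4mer, f.kl_codon, s.decision_score, False, np.nan, np.nan, TYPICAL))
        else:
            c = by_id[g.gene_id]
            rows.append(
                (
                    g.gene_id,
                    f.chi2_4mer,
                    f.kl_codon,
                    s.decision_score,
                    True,
                    np.nan if c.loglik is None else c.loglik,
                    np.nan if c.membership_hgt is None else c.membership_hgt,
                    c.call,
                )
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def detect(
    genes: Sequence[GeneRecord],
    query_proteome: Proteome,
    pool: Sequence[tuple[TaxonomyRecord, Proteome]],
    query_tax: TaxonomyRecord,
    config: RunConfig = RunConfig(),
    shadow: Sequence[ShadowSpecies] | None = None,
    precomputed: dict[str, IdentityVector] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full detector in memory; returns the results table + extras.

    A pre-fitted ``shadow`` (and per-gene identity vectors) can be supplied
    to amortize alignment work across parameter sweeps.
    """
    features = feature_table(genes, pseudocount=config.pseudocount)
    svm_calls = fit_predict_atypical(features, SvmConfig(nu=config.nu, seed=config.seed))
    atypical = [g for g, c in zip(genes, svm_calls) if c.is_atypical]
    logger.info("stage i: %d / %d genes atypical at nu=%.2f", len(atypical), len(genes), config.nu)

    hgt_calls: list[HGTCall] = []
    if atypical:
        if shadow is None:
            shadow = fit_shadow_model(query_proteome, pool, query_tax, config)
        hgt_calls = phylogenetic_stage(atypical, shadow, config, precomputed)
    results = _results_frame(genes, features, svm_calls, hgt_calls)
    extras = {"features": features, "svm_calls": svm_calls, "shadow": shadow or [], "hgt_calls": hgt_calls}
    return results, extras


def run_shadowcaster(
    cds_path: str | Path,
    proteome_path: str | Path,
    proteome_dir: str | Path,
    taxonomy_path: str | Path,
    out_dir: str | Path,
    query_species: str | None = None,
    config: RunConfig = RunConfig(),
) -> pd.DataFrame:
    """File-level entry point: read inputs, run all stages, write outputs.

    Writes features.tsv, atypical.tsv, shadow_manifest.tsv, results.tsv,
    hgt_genes.fna and manifest.json under ``out_dir``.  Reruns with the same
    inputs and config reproduce the outputs bit for bit.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genes = read_cds_fasta(cds_path)
    query_proteome = read_proteome_fasta(proteome_path)
    taxonomy = {t.species_id: t for t in read_taxonomy_table(taxonomy_path)}
    qid = query_species or query_proteome.species_id
    if qid not in taxonomy:
        raise ValueError(f"query species {qid!r} not in the taxonomy table")
    query_tax = taxonomy[qid]

    pool: list[tuple[TaxonomyRecord, Proteome]] = []
    for f in sorted(Path(proteome_dir).glob("*.fa*")):
        prot = read_proteome_fasta(f)
        if prot.species_id == qid:
            continue
        if prot.species_id not in taxonomy:
            raise ValueError(f"pool species {prot.species_id!r} not in the taxonomy table")
        pool.append((taxonomy[prot.species_id], prot))

    results, extras = detect(genes, query_proteome, pool, query_tax, config)

    write_feature_table(extras["features"], out / "features.tsv")
    write_atypical_calls(extras["svm_calls"], out / "atypical.tsv")
    if extras["shadow"]:
        write_shadow_manifest(extras["shadow"], out / "shadow_manifest.tsv")
    results.round(6).to_csv(out / "results.tsv", sep="\t", index=False, na_rep="NA")
    hgt_ids = set(results.loc[results["call"] == "HGT", "gene_id"])
    write_cds_fasta([g for g in genes if g.gene_id in hgt_ids], out / "hgt_genes.fna")
    manifest = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "n_genes": len(genes),
        "n_atypical": int(results["is_atypical"].sum()),
        "n_hgt": len(hgt_ids),
        "inputs": {
            "cds": str(cds_path),
            "proteome": str(proteome_path),
            "proteome_dir": str(proteome_dir),
            "taxonomy": str(taxonomy_path),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return results
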