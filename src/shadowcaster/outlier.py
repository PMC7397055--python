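"""Unsupervised atypical-gene calling with a one-class SVM.

The two compositional features are z-scored and fed to a one-class SVM
with an RBF kernel, trained on all genes.  The nu parameter upper-bounds
the fraction of training errors (and lower-bounds the fraction of support
vectors), so it directly controls how aggressively genes are flagged.
Genes with a negative signed decision score are the atypical set passed to
the phylogenetic stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.svm import OneClassSVM

from .composition import FeatureVector


@dataclass(frozen=True)
class SvmConfig:
    nu: float = 0.4
    kernel: str = "rbf"
    gamma_rule: str = "scale"
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.nu <= 1:
            raise ValueError(f"nu must be in (0, 1], got {self.nu}")


@dataclass(frozen=True)
class AtypicalCall:
    gene_id: str
    decision_score: float
    is_atypical: bool


def fit_predict_atypical(
    features: Sequence[FeatureVector], config: SvmConfig = SvmConfig()
) -> list[AtypicalCall]:
    """Train on all genes, return a signed score and outlier flag per gene.

    The model is fitted on rows sorted by gene_id so the result is invariant
    to input order; scores are reported in the input order.  Zero-variance
    feature columns are centered but not scaled.
    """
    if len(features) < 10:
        raise ValueError(f"need >= 10 genes for outlier detection, got {len(features)}")
    X = np.array([[f.chi2_4mer, f.kl_codon] for f in features], dtype=float)
    for f, row in zip(features, X):
        if not np.all(np.isfinite(row)):
            raise ValueError(f"gene {f.gene_id!r} has a non-finite feature")

    if config.standardize:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0  # zero-variance column: center only
        X = (X - mean) / std

    order = np.argsort([f.gene_id for f in features], kind="stable")
    # the dual problem is degenerate at exactly nu=1; clamp just below
    nu = min(config.nu, 1.0 - 1e-9)
    svm = OneClassSVM(nu=nu, kernel=config.kernel.lower(), gamma=config.gamma_rule)
    svm.fit(X[order])
    scores = svm.decision_function(X)
    return [
        AtypicalCall(gene_id=f.gene_id, decision_score=float(s), is_atypical=bool(s < 0))
        for f, s in zip(features, scores)
    ]


def write_atypical_calls(calls: Sequence[AtypicalCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tdecision_score\tis_atypical\n")
        for c in calls:
            fh.write(f"{c.gene_id}\t{c.decision_score:.6f}\t{str(c.is_atypical).lower()}\n")
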