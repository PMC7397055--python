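"""Simulated transfer experiments: nu and shadow-size sweeps.

A :class:`TransferExperiment` caches everything about one simulated dataset
that is independent of the SVM's nu — the compositional features, the
fitted shadow, and best-hit identity vectors for every admissible gene —
so sweeping nu (or re-calling at one nu) costs only the SVM fit, the
likelihood arithmetic and the fuzzy split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .composition import FeatureVector, feature_table
from .inference import IdentityVector, identity_vectors
from .outlier import SvmConfig, fit_predict_atypical
from .pipeline import RunConfig, detect, fit_shadow_model, phylogenetic_stage, _results_frame
from .shadow import ShadowSpecies
from .simulate import SimulatedDataset, simulate_dataset, score_calls


@dataclass
class TransferExperiment:
    dataset: SimulatedDataset
    config: RunConfig
    features: list[FeatureVector] = field(default_factory=list)
    shadow: list[ShadowSpecies] = field(default_factory=list)
    identity_cache: dict[str, IdentityVector] = field(default_factory=dict)

    @classmethod
    def prepare(
        cls,
        donor: str = "far",
        n_genes: int = 500,
        seed: int = 0,
        n_shadow: int = 15,
        **config_kwargs,
    ) -> "TransferExperiment":
        """Simulate one dataset and cache its nu-independent stages."""
        ds = simulate_dataset(donor=donor, n_genes=n_genes, seed=seed)
        cfg = RunConfig(n_shadow=n_shadow, seed=seed, **config_kwargs)
        exp = cls(dataset=ds, config=cfg)
        exp.features = feature_table(ds.genome, pseudocount=cfg.pseudocount)
        exp.shadow = fit_shadow_model(ds.proteome, ds.shadow_pool, ds.query_taxonomy, cfg)
        ivs = identity_vectors(ds.genome, exp.shadow, min_len_aa=cfg.min_aa)
        exp.identity_cache = {iv.gene_id: iv for iv in ivs}
        return exp

    def evaluate(self, nu: float):
        """Calls and (TPR, FPR) of the full detector at one nu value."""
        import dataclasses

        cfg = dataclasses.replace(self.config, nu=nu)
        svm_calls = fit_predict_atypical(self.features, SvmConfig(nu=nu, seed=cfg.seed))
        atypical = [g for g, c in zip(self.dataset.genome, svm_calls) if c.is_atypical]
        hgt_calls = phylogenetic_stage(atypical, self.shadow, cfg, precomputed=self.identity_cache)
        results = _results_frame(self.dataset.genome, self.features, svm_calls, hgt_calls)
        tpr, fpr = score_calls(results, self.dataset.truth)
        return results, tpr, fpr


def run_once(donor: str, seed: int, nu: float = 0.4, n_shadow: int = 15, n_genes: int = 500):
    """One fresh end-to-end run; returns (results, TPR, FPR)."""
    ds = simulate_dataset(donor=donor, n_genes=n_genes, seed=seed)
    cfg = RunConfig(nu=nu, n_shadow=n_shadow, seed=seed)
    results, _ = detect(ds.genome, ds.proteome, ds.shadow_pool, ds.query_taxonomy, cfg)
    tpr, fpr = score_calls(results, ds.truth)
    return results, tpr, fpr


def median_rates(donor: str, seeds, nu: float = 0.4, n_shadow: int = 15, n_genes: int = 500):
    """Median (TPR, FPR) of fresh runs over several seeds."""
    rates = [run_once(donor, s, nu, n_shadow, n_genes)[1:] for s in seeds]
    tprs, fprs = zip(*rates)
    return float(np.median(tprs)), float(np.median(fprs))
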