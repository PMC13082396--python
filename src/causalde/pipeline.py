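"""End-to-end orchestration: counts + design in, effect table + diagnostics out.

Stages: size factors -> dispersions -> factor model (fixed rank or JIC
selection) -> nuisance models -> AIPW imputation -> per-gene tests with
FDR/FDX control. A machine-readable manifest (config, seed, version) and a
diagnostics dict (overlap, convergence, JIC path) accompany the results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .containers import CountMatrix, DesignMatrix, GeneEffectTable
from .effects import AIPWEffects, PotentialOutcomes
from .factor import (
    DEFAULT_JIC_NU,
    FactorFit,
    estimate_dispersion,
    fit_factor_model,
    select_rank,
)
from .io import estimate_size_factors, write_results

logger = logging.getLogger(__name__)

__all__ = ["FactorConfig", "CausalConfig", "PipelineConfig", "PipelineResult", "run_pipeline"]


def _from_dict(cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class FactorConfig:
    rank: int = 4
    rank_grid: Optional[list] = None
    max_iter: int = 100
    tol: float = 1e-4
    jic_nu: float = DEFAULT_JIC_NU
    phi_bounds: tuple = (0.01, 100.0)
    seed: int = 0


@dataclass
class CausalConfig:
    propensity: str = "logistic"
    clip: float = 0.01
    folds: int = 5
    tune_propensity: bool = False
    fdr_alpha: float = 0.1
    fdx_gamma: float = 0.1
    fdx_alpha: float = 0.05
    variance: str = "standard"
    debias: bool = True
    empirical_null: bool = True
    size_factor_method: str = "median_of_ratios"


@dataclass
class PipelineConfig:
    factor: FactorConfig = field(default_factory=FactorConfig)
    causal: CausalConfig = field(default_factory=CausalConfig)
    seed: int = 0
    out_dir: Optional[str] = None
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        factor = _from_dict(FactorConfig, data.pop("factor", {}) or {})
        causal = _from_dict(CausalConfig, data.pop("causal", {}) or {})
        known = {"seed", "out_dir", "log_level"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        return cls(factor=factor, causal=causal, **data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    table: GeneEffectTable
    factor_fit: FactorFit
    potential_outcomes: PotentialOutcomes
    diagnostics: dict


def run_pipeline(
    cm: CountMatrix, design: DesignMatrix, cfg: Optional[PipelineConfig] = None
) -> PipelineResult:
    """Run the full causal DE pipeline; stage names annotate any failure."""
    cfg = cfg or PipelineConfig()
    stage = "size_factors"
    try:
        if cm.size_factors is None:
            estimate_size_factors(cm, method=cfg.causal.size_factor_method)
        stage = "dispersion"
        dispersions = estimate_dispersion(cm, design, cfg.factor.phi_bounds)
        stage = "factor_model"
        jic_path = None
        rank = cfg.factor.rank
        factor_opts = dict(
            max_iter=cfg.factor.max_iter,
            tol=cfg.factor.tol,
            jic_nu=cfg.factor.jic_nu,
            phi_bounds=tuple(cfg.factor.phi_bounds),
            random_state=cfg.factor.seed,
        )
        if cfg.factor.rank_grid:
            rank, jic_path = select_rank(
                cm, design, cfg.factor.rank_grid, dispersions=dispersions, **factor_opts
            )
        fit = fit_factor_model(cm, design, rank, dispersions=dispersions, **factor_opts)
        # the factor model's row intercepts refine the plug-in size factors;
        # the causal stage works on the same effective scale
        cm.size_factors = fit.size_factors
        stage = "causal_effects"
        est = AIPWEffects(
            propensity=cfg.causal.propensity,
            clip=cfg.causal.clip,
            folds=cfg.causal.folds,
            tune_propensity=cfg.causal.tune_propensity,
            fdr_alpha=cfg.causal.fdr_alpha,
            fdx_gamma=cfg.causal.fdx_gamma,
            fdx_alpha=cfg.causal.fdx_alpha,
            variance=cfg.causal.variance,
            debias=cfg.causal.debias,
            empirical_null=cfg.causal.empirical_null,
            random_state=cfg.seed,
        )
        est.fit(
            cm,
            design,
            confounders=fit.U_causal if rank > 0 else None,
            dispersions=fit.dispersions,
            loadings=fit.Gamma if rank > 0 else None,
        )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    table = est.to_table()
    diagnostics = {
        "rank": int(rank),
        "jic": float(fit.jic),
        "jic_path": jic_path,
        "factor_converged": bool(fit.converged),
        "loglik_final": float(fit.loglik_trace[-1]),
        "clipped_propensity_fraction": est.clipped_fraction_,
        "n_flagged_outcome_genes": int(est.outcome_fit_.flagged.sum()),
        "n_nan_effects": int(np.isnan(est.tau_).sum()),
    }
    result = PipelineResult(
        table=table, factor_fit=fit, potential_outcomes=est.potential_outcomes_,
        diagnostics=diagnostics,
    )
    if cfg.out_dir:
        _write_outputs(result, cfg)
    return result


def _write_outputs(result: PipelineResult, cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_results(result.table, out / "effects.tsv")
    cfg_dict = cfg.to_dict()
    manifest = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": cfg.seed,
        "package": "causalde 0.1.0",
        "diagnostics": {
            k: v for k, v in result.diagnostics.items() if not isinstance(v, dict)
        },
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
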