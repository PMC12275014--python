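"""End-to-end orchestration of the extreme normative modeling workflow.

Stages, in order: (1) normative fits per phenotype on a training split,
(2) held-out deviation z-scores assembled into a matrix, (3) rank/Frechet
marginal transform, (4) polar decomposition and radial thresholding,
(5) TPDM estimation and extreme PCA, (6) association of component scores
with behavioral phenotypes (with standard-PCA and count-score comparators).
Every intermediate artifact is written as labeled CSV and listed, with a
checksum, in a JSON run manifest, so a run is reproducible from its config
and seed alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import evt_multivariate as mev
from . import synthetic
from .normative import NormativeConfig, fit_zscore_matrix

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

PIPELINE_VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    """Single-document configuration for a full run."""

    output_dir: str
    seed: int = 0
    # input paths; leave None to use the synthetic block
    covariates_path: str | None = None
    idps_path: str | None = None
    zscores_path: str | None = None
    phenotypes_path: str | None = None
    synthetic: dict | None = None
    # normative options
    train_fraction: float = 0.1
    warp: bool = False
    qc: bool = False
    # EVT options
    quantile: float = 0.95
    normalization: str = "unit"
    n_components: int = 2
    score_map: str = "log"
    loading_mode: str = "printed"
    # association options
    alpha: float = 0.05

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must lie in (0, 1)")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.synthetic is None:
            if self.zscores_path is None and (self.covariates_path is None
                                              or self.idps_path is None):
                raise ValueError("provide either a synthetic block, a zscores_path, "
                                 "or covariates_path + idps_path")
            for name in ("covariates_path", "idps_path", "zscores_path",
                         "phenotypes_path"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise ValueError(f"{name} does not exist: {p}")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML (or JSON) config file into a validated PipelineConfig."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    manifest["artifacts"][path.name] = _sha256(path)


def _simulate_inputs(cfg: PipelineConfig, outdir: Path, manifest: dict):
    """Generate covariates/IDPs, tail-dependent z-scores, and phenotypes."""
    syn = dict(cfg.synthetic or {})
    n = int(syn.get("n_subjects", 5000))
    B = np.asarray(syn.get("maxlinear_B",
                           [[1.0, 0.0], [0.8, 0.6], [0.0, 1.0]]), dtype=float)
    spec = synthetic.MaxLinearSpec(B)
    rng = np.random.default_rng(cfg.seed)
    z = synthetic.gen_tail_dependent_zscores(n, spec, seed=int(rng.integers(2**31)))

    # ground-truth component scores from the oracle TPDM's eigenbasis,
    # used only to plant phenotype effects
    x = mev.to_pseudo_frechet(z)
    oracle = mev.TPDM(matrix=spec.oracle_tpdm(), normalization="unit",
                      radial_threshold=np.nan, n_exceedances=0, columns=x.columns)
    basis_true = mev.extreme_pca(oracle)
    true_scores = mev.project_scores(x, basis_true, n_components=cfg.n_components,
                                     score_map=cfg.score_map)

    ph_spec_raw = syn.get("phenotypes", {"n_null": 50, "planted": []})
    planted = tuple(synthetic.PlantedEffect(**p) for p in ph_spec_raw.get("planted", []))
    ph_spec = synthetic.PhenotypeSpec(n_null=int(ph_spec_raw.get("n_null", 0)),
                                      planted=planted)
    phenotypes = synthetic.gen_phenotypes(true_scores, ph_spec,
                                          seed=int(rng.integers(2**31)))
    _write_csv(z, outdir / "zscores.csv", manifest)
    _write_csv(phenotypes, outdir / "phenotypes.csv", manifest)
    manifest["stages"]["simulate"] = {
        "n_subjects": n, "maxlinear_B": B.tolist(),
        "oracle_tpdm": spec.oracle_tpdm().tolist(),
        "phenotype_spec": {"n_null": ph_spec.n_null,
                           "planted": [asdict(p) for p in ph_spec.planted]},
    }
    return z, phenotypes


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return the run manifest (also written as JSON)."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "pipeline_version": PIPELINE_VERSION,
        "seed": config.seed,
        "config": asdict(config),
        "artifacts": {},
        "stages": {},
    }

    # ---- stages 1-2: obtain the z-score matrix ----------------------------
    phenotypes = None
    if config.synthetic is not None:
        z, phenotypes = _simulate_inputs(config, outdir, manifest)
    elif config.zscores_path is not None:
        z = pd.read_csv(config.zscores_path)
        manifest["stages"]["normative"] = {"skipped": "precomputed z-scores supplied"}
    else:
        covariates = pd.read_csv(config.covariates_path)
        idps = pd.read_csv(config.idps_path)
        z, metrics, _ = fit_zscore_matrix(
            covariates, idps, NormativeConfig(warp=config.warp),
            train_fraction=config.train_fraction, seed=config.seed, qc=config.qc)
        _write_csv(z, outdir / "zscores.csv", manifest)
        _write_csv(metrics, outdir / "normative_metrics.csv", manifest)
        manifest["stages"]["normative"] = {
            "train_fraction": config.train_fraction, "warp": config.warp,
            "n_variables_fit": int(len(metrics)),
            "n_variables_excluded": int((~metrics["qc_pass"]).sum()) if config.qc else 0,
        }
    if phenotypes is None and config.phenotypes_path is not None:
        phenotypes = pd.read_csv(config.phenotypes_path)

    # ---- stages 3-4: marginal transform, polar threshold ------------------
    x = mev.to_pseudo_frechet(z)
    polar = mev.polar_decompose_threshold(x, quantile=config.quantile)
    manifest["stages"]["threshold"] = {
        "quantile": config.quantile,
        "radial_threshold": polar.radial_threshold,
        "n_exceedances": polar.n_exceedances,
        "n_rows_dropped_missing": x.n_dropped_rows,
    }

    # ---- stage 5: TPDM and extreme PCA ------------------------------------
    tpdm = mev.estimate_tpdm(polar, normalization=config.normalization)
    basis = mev.extreme_pca(tpdm)
    L = min(config.n_components, len(basis.eigenvalues))
    f, c = mev.loadings_contributions(basis, L, mode=config.loading_mode)
    scores = mev.project_scores(x, basis, L, score_map=config.score_map)

    tpdm_df = tpdm.as_frame().reset_index(names="variable")
    _write_csv(tpdm_df, outdir / "tpdm.csv", manifest)
    eig_df = pd.DataFrame({
        "component": np.arange(len(basis.eigenvalues)),
        "eigenvalue": basis.eigenvalues,
        "scale_proportion": basis.scale_proportions,
    })
    _write_csv(eig_df, outdir / "eigenvalues.csv", manifest)
    tidy = []
    for l in range(L):
        for d_i, var in enumerate(basis.columns):
            tidy.append((var, l, basis.eigenvectors[d_i, l], f[d_i, l], c[d_i, l]))
    _write_csv(pd.DataFrame(tidy, columns=["variable", "component", "eigenvector",
                                           "loading", "contribution"]),
               outdir / "loadings_contributions.csv", manifest)
    scores_df = pd.DataFrame(scores, columns=[f"extreme_pc_{l}" for l in range(L)])
    if "subject_id" in z.columns:
        scores_df.insert(0, "subject_id", z["subject_id"].to_numpy()[
            np.all(np.isfinite(z.drop(columns="subject_id").to_numpy(dtype=float)),
                   axis=1)])
    _write_csv(scores_df, outdir / "extreme_scores.csv", manifest)
    manifest["stages"]["extreme_pca"] = {
        "normalization": config.normalization, "score_map": config.score_map,
        "n_components": L,
        "scale_proportions": basis.scale_proportions[:L].tolist(),
        "average_contribution_line": 1.0 / len(basis.columns),
    }

    # comparators
    std_scores, std_U, std_props = assoc.standard_pca_baseline(z, L)
    std_df = pd.DataFrame(std_scores, columns=[f"standard_pc_{l}" for l in range(L)])
    _write_csv(std_df, outdir / "standard_pca_scores.csv", manifest)
    counts = assoc.deviation_count_score(z)
    _write_csv(counts, outdir / "count_scores.csv", manifest)
    manifest["stages"]["comparators"] = {
        "standard_pca_variance_proportions": std_props[:L].tolist(),
        "count_cutoff": 1.96,
    }

    # ---- stage 6: associations --------------------------------------------
    if phenotypes is not None:
        table = assoc.associate_components(scores, phenotypes, alpha=config.alpha,
                                           n_components=L)
        _write_csv(table, outdir / "associations_extreme.csv", manifest)
        _write_csv(assoc.aggregate_by_phenotype(table),
                   outdir / "associations_extreme_aggregate.csv", manifest)
        table_std = assoc.associate_components(std_scores, phenotypes,
                                               alpha=config.alpha, n_components=L)
        _write_csv(table_std, outdir / "associations_standard.csv", manifest)
        manifest["stages"]["association"] = {
            "alpha": config.alpha,
            "n_tests": int(table["n_tests"].iloc[0]) if len(table) else 0,
            "n_significant_extreme": int(table["bonferroni_significant"].sum()),
            "n_significant_standard": int(table_std["bonferroni_significant"].sum()),
        }

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
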