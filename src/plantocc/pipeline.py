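"""End-to-end orchestration of the six analysis variants.

Model 1 (per-species frequencies) and Model 2 (covariate effects) are each
fit three ways: on the original data (variant 1), with random imputation of
mentioned records (variant 2), and with posterior imputation (variant 3).
Variant 3 consumes the posterior of variant 1's fit, so run order is fixed.
All seeds derive from one master seed through numpy SeedSequence spawning.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from plantocc import __version__
from plantocc.data import (
    ENV_COLUMNS,
    env_design,
    load_records,
    load_species,
    collinearity_screen,
    species_design,
)
from plantocc.models import MCMCConfig, build_model1, build_model2
from plantocc.nuts import ModelFit, fit as nuts_fit
from plantocc.phylo import patristic_distances, pcoa, pv_design, read_newick
from plantocc.imputation import replicate_fit_and_pool
from plantocc.summary import (
    RopeSpec,
    posterior_predictive,
    summarize_coefficients,
    summarize_species,
)

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "compare_methods"]

DEFAULT_CONFIG: dict = {
    "models": [1, 2],
    "methods": ["none", "random", "posterior"],
    "chains": 4,
    "iterations": 5000,
    "warmup": 2000,
    "imputed_iterations": 2000,
    "imputed_warmup": 1500,
    "n_replicates": 10,
    "thin_rate": 0.5,
    "n_pv_axes": None,  # None = broken-stick retention
    "center_species_design": False,
    "log_base_body_mass": "e",
    "bin_width_model1": 0.005,
    "bin_width_model2": 0.01,
    "pooled_bins": False,
    "collinearity_threshold": 0.80,
    "rope": (-0.1, 0.1),
    "hdi_mass": 0.89,
    "rope_convention": "draws",
    "rhat_threshold": 1.01,
    "target_accept": 0.8,
    "max_treedepth": 10,
    "save_draws": False,
    "ppc_draws": 500,
}


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _seed_from(stream: np.random.SeedSequence) -> int:
    return int(stream.generate_state(1)[0] % (2**31))


def _float_fmt(frame: pd.DataFrame) -> pd.DataFrame:
    return frame


def compare_methods(summaries: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Concordance report across imputation methods for one model.

    Input maps method name -> coefficient summary table.  Output has one row
    per parameter with MAP/EAP/verdicts per method and a flag when the
    significance verdicts disagree across methods.
    """
    if len(summaries) < 2:
        raise ValueError("compare_methods needs at least two completed runs")
    methods = list(summaries)
    base = summaries[methods[0]][["parameter"]].copy()
    for m in methods:
        s = summaries[m].set_index("parameter")
        base[f"MAP_{m}"] = s["MAP"].reindex(base["parameter"]).to_numpy()
        base[f"EAP_{m}"] = s["EAP"].reindex(base["parameter"]).to_numpy()
        if "significant_rope" in s.columns:
            base[f"sig_rope_{m}"] = (
                s["significant_rope"].reindex(base["parameter"]).to_numpy()
            )
            base[f"sig_ci_{m}"] = (
                s["significant_ci"].reindex(base["parameter"]).to_numpy()
            )
    rope_cols = [c for c in base.columns if c.startswith("sig_rope_")]
    ci_cols = [c for c in base.columns if c.startswith("sig_ci_")]
    if rope_cols:
        base["verdicts_disagree"] = base[rope_cols].nunique(axis=1).gt(1) | base[
            ci_cols
        ].nunique(axis=1).gt(1)
    return base


def run_pipeline(
    record_csv: str | Path,
    species_csv: str | Path,
    tree_newick: str | Path,
    config: dict | None = None,
    outdir: str | Path | None = None,
    seed: int = 0,
) -> Path:
    """Run the configured analysis variants and write all artifacts.

    Returns the output directory.  Inputs are never mutated; a manifest with
    input digests, the config snapshot and all derived seeds is written even
    when a fit fails mid-run.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    if outdir is None:
        stamp = datetime.datetime.now().strftime("%Y%m%d-%H%M%S")
        outdir = Path(f"plantocc-run-{stamp}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "master_seed": seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()},
        "inputs": {
            "records": str(record_csv),
            "species": str(species_csv),
            "tree": str(tree_newick),
        },
        "digests": {
            "records": _digest(record_csv),
            "species": _digest(species_csv),
            "tree": _digest(tree_newick),
        },
        "runs": [],
        "status": "started",
    }

    def write_manifest() -> None:
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str)
        )

    write_manifest()
    try:
        _run(cfg, record_csv, species_csv, tree_newick, outdir, seed, manifest)
        manifest["status"] = "completed"
    except Exception as exc:
        manifest["status"] = f"failed: {exc!r}"
        write_manifest()
        raise
    write_manifest()
    return outdir


def _run(cfg, record_csv, species_csv, tree_newick, outdir, seed, manifest):
    rope = RopeSpec(*cfg["rope"])
    species_table = load_species(species_csv)
    records = load_records(record_csv, known_species=set(species_table.index))
    tree = read_newick(str(tree_newick))

    # --- covariate preparation + collinearity screen ----------------------
    env = env_design(records)
    flagged = collinearity_screen(env, threshold=cfg["collinearity_threshold"])
    pairs = [
        {"a": a, "b": b, "r": r}
        for a, b, r in flagged
        if not (np.isnan(r))
    ]
    undefined = [{"a": a, "b": b} for a, b, r in flagged if np.isnan(r)]
    (outdir / "collinearity.json").write_text(
        json.dumps({"flagged": pairs, "undefined_correlation": undefined}, indent=2)
    )
    for item in pairs:
        warnings.warn(
            f"collinearity screen: |r({item['a']}, {item['b']})| = "
            f"{abs(item['r']):.3f} >= {cfg['collinearity_threshold']}"
        )

    # --- PVR --------------------------------------------------------------
    es = pcoa(patristic_distances(tree))
    es.eigenvalue_table().to_csv(outdir / "pvr_eigenvalues.csv", index=False)
    species_order = sorted({r.species_id for r in records})
    pv = pv_design(es, n_axes=cfg["n_pv_axes"], species_order=species_order)
    pv.to_csv(outdir / "pv_design.csv")
    sp_design = species_design(
        species_table.loc[species_order], pv,
        center=cfg["center_species_design"],
    )

    master = np.random.SeedSequence(seed)
    streams = {
        name: s
        for name, s in zip(
            ["m1_1", "m2_1", "m1_2", "m1_3", "m2_2", "m2_3", "ppc"],
            master.spawn(7),
        )
    }

    base_config = dict(
        chains=cfg["chains"],
        rhat_threshold=cfg["rhat_threshold"],
        target_accept=cfg["target_accept"],
        max_treedepth=cfg["max_treedepth"],
    )

    def make_config(stream, imputed: bool) -> MCMCConfig:
        return MCMCConfig(
            iterations=cfg["imputed_iterations"] if imputed else cfg["iterations"],
            warmup=cfg["imputed_warmup"] if imputed else cfg["warmup"],
            seed=_seed_from(stream),
            **base_config,
        )

    env_mat = env.to_numpy(dtype=float)
    sp_mat = sp_design.to_numpy(dtype=float)
    sp_names = list(sp_design.columns)

    def model1_factory(recs, include_psi=True):
        return build_model1(recs, include_psi=include_psi,
                            species_labels=species_order)

    def model2_factory(recs, include_psi=True):
        return build_model2(
            recs, env_mat, sp_mat, species_order,
            include_psi=include_psi,
            env_names=list(ENV_COLUMNS), sp_names=sp_names,
        )

    fits: dict[str, ModelFit] = {}
    summaries: dict[int, dict[str, pd.DataFrame]] = {1: {}, 2: {}}

    def finalize(tag: str, model_id: int, fit: ModelFit, method: str) -> None:
        fit.meta.update(
            {
                "species_labels": species_order,
                "env_names": list(ENV_COLUMNS),
                "sp_names": sp_names,
                "record_ids": [r.record_id for r in records],
                "model": model_id,
                "method": method,
            }
        )
        fits[tag] = fit
        sp_summary = summarize_species(fit, species_order)
        sp_summary.to_csv(outdir / f"{tag}_species_frequency.csv", index=False)
        out = {"species": str(outdir / f"{tag}_species_frequency.csv")}
        if model_id == 2:
            coef = summarize_coefficients(
                fit, rope=rope, hdi_mass=cfg["hdi_mass"],
                rope_convention=cfg["rope_convention"],
            )
            coef.to_csv(outdir / f"{tag}_coefficients.csv", index=False)
            summaries[2][method] = coef
            out["coefficients"] = str(outdir / f"{tag}_coefficients.csv")
        else:
            summaries[1][method] = sp_summary.rename(
                columns={"species_id": "parameter"}
            )
        if cfg["save_draws"]:
            fit.save(outdir / f"{tag}_draws.csv")
        manifest["runs"].append(
            {
                "tag": tag,
                "model": model_id,
                "method": method,
                "seed": fit.config.seed,
                "converged": fit.converged,
                "max_rhat": max(fit.diagnostics.get("rhat", {"": np.nan}).values()),
                "outputs": out,
            }
        )

    factories = {1: model1_factory, 2: model2_factory}
    bin_widths = {1: cfg["bin_width_model1"], 2: cfg["bin_width_model2"]}

    # --- non-imputed fits (needed first: variant 3 consumes their posterior)
    for model_id in cfg["models"]:
        if "none" not in cfg["methods"]:
            continue
        tag = f"model{model_id}_1"
        config = make_config(streams[f"m{model_id}_1"], imputed=False)
        fit = nuts_fit(factories[model_id](records), config)
        finalize(tag, model_id, fit, "none")

    # --- imputed, pooled fits ---------------------------------------------
    variant = {"random": 2, "posterior": 3}
    for model_id in cfg["models"]:
        for method in cfg["methods"]:
            if method == "none":
                continue
            source = fits.get(f"model{model_id}_1")
            if source is None:
                raise ValueError(
                    "imputed variants require the non-imputed fit of the same model"
                )
            tag = f"model{model_id}_{variant[method]}"
            config = make_config(
                streams[f"m{model_id}_{variant[method]}"], imputed=True
            )
            fit = replicate_fit_and_pool(
                records,
                lambda recs, m=model_id: factories[m](recs, include_psi=False),
                method=method,
                config=config,
                psi_source=source,
                n_replicates=cfg["n_replicates"],
                bin_width=bin_widths[model_id],
                thin_rate=cfg["thin_rate"],
                pooled_bins=cfg["pooled_bins"],
            )
            finalize(tag, model_id, fit, method)

    # --- posterior predictive checks on the non-imputed fits ---------------
    ppc_seed = _seed_from(streams["ppc"])
    for model_id in cfg["models"]:
        tag = f"model{model_id}_1"
        if tag in fits:
            ppc = posterior_predictive(
                fits[tag], records, seed=ppc_seed, max_draws=cfg["ppc_draws"]
            )
            ppc.to_csv(outdir / f"{tag}_ppc.csv", index=False)

    # --- concordance across methods ----------------------------------------
    for model_id in cfg["models"]:
        if len(summaries[model_id]) >= 2:
            compare_methods(summaries[model_id]).to_csv(
                outdir / f"model{model_id}_method_concordance.csv", index=False
            )
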