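"""Scenario-grid orchestration: genotypes -> traits -> model fits ->
heritability and prediction-accuracy records.

Configuration is a single YAML/dict with the scenario grid, model list,
MCMC settings and a master seed.  Every stage derives its own seed from the
master seed through ``np.random.SeedSequence`` keyed on the stage name and
grid coordinates, so two runs with the same config produce bit-identical
result records; the manifest echoes all derived seeds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import accuracy, aggregate, make_splits, pairwise_method_comparison, training_r2
from .genotype_sim import (
    COMMON_MARKER_LAW,
    LOW_MAF_POOL_LAW,
    PANEL_MIXTURE_LAW,
    GenotypeMatrix,
    HaplotypePoolSpec,
    MAFLaw,
    simulate_genotypes,
)
from .heritability import estimate_h2
from .ld_kinship import compute_grm
from .plink_io import read_plink
from .qc import apply_qc, mean_impute
from .trait_sim import ArchitectureSpec, simulate_scenario_trait
from .wgr_models import MCMCConfig, fit_bayes_a, fit_gblup, fit_spike_slab, predict

_STAGE_TAGS = {"genotypes": 1, "partition": 2, "splits": 3, "trait": 4, "fit": 5}
_METHODS = ("gblup", "bayes_a", "spike_slab")
_DATA_USED = ("markers", "markers_qtl", "qtl")

DEFAULT_CONFIG: dict = {
    "seed": 20150120,
    "genotypes": {
        "n_individuals": 300,
        "n_founder_haplotypes": 200,
        "n_blocks": 12,
        "markers_per_block": 25,
        "switch_prob": 0.05,
        "maf_law": "panel_mixture",
    },
    "panel": {"n_markers": 200, "n_qtl": 40},
    "schemes": ["RAND", "LOW_MAF"],
    "architectures": [
        {"n_large": 0, "pve_large": 0.0},
        {"n_large": 4, "pve_large": 0.25},
        {"n_large": 20, "pve_large": 0.75},
    ],
    "target_h2": 0.5,
    "residual_variance": 0.5,
    "data_used": list(_DATA_USED),
    "methods": list(_METHODS),
    "replicates": 2,
    "validation": {"n_candidates": 50, "threshold": 0.125},
    "mcmc": {"n_iter": 1500, "burn_in": 500, "thin": 5},
    "qc": {"snp_miss_max": 0.01, "ind_miss_max": 0.05, "maf_min": 0.01},
}

_NAMED_LAWS = {
    "common_marker": COMMON_MARKER_LAW,
    "low_maf_pool": LOW_MAF_POOL_LAW,
    "panel_mixture": PANEL_MIXTURE_LAW,
}


def derive_seed(master: int, stage: str, *coords: int) -> int:
    """Documented per-stage seed derivation (always below 2^31)."""
    entropy = [int(master), _STAGE_TAGS[stage], *[int(c) for c in coords]]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def maf_law_from_config(spec) -> MAFLaw:
    if isinstance(spec, MAFLaw):
        return spec
    if isinstance(spec, str):
        return _NAMED_LAWS[spec]
    spec = dict(spec)
    if spec.get("family") == "mixture":
        comps = tuple(maf_law_from_config(c) for c in spec["components"])
        return MAFLaw("mixture", components=comps, weights=tuple(spec["weights"]))
    return MAFLaw(**spec)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    loaded = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
    for source in (loaded, overrides or {}):
        for key, val in source.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def pool_spec_from_config(cfg: dict, seed: int) -> HaplotypePoolSpec:
    g = cfg["genotypes"]
    return HaplotypePoolSpec(
        n_founder_haplotypes=g.get("n_founder_haplotypes", 200),
        n_blocks=g["n_blocks"],
        markers_per_block=g["markers_per_block"],
        within_block_switch_prob=g.get("switch_prob", 0.05),
        maf_law=maf_law_from_config(g.get("maf_law", "panel_mixture")),
        seed=seed,
    )


def mcmc_from_config(cfg: dict, seed: int) -> MCMCConfig:
    m = cfg.get("mcmc", {})
    return MCMCConfig(
        n_iter=m.get("n_iter", 12_000),
        burn_in=m.get("burn_in", 2_000),
        thin=m.get("thin", 5),
        seed=seed,
    )


def _load_panel(cfg: dict) -> tuple[GenotypeMatrix, np.ndarray, dict | None]:
    """Simulated panel, or a PLINK panel passed through quality control."""
    g = cfg["genotypes"]
    if g.get("plink_prefix"):
        G, mask = read_plink(g["plink_prefix"])
        qc_cfg = cfg.get("qc", {})
        G, mask, report = apply_qc(G, mask, **qc_cfg)
        X = mean_impute(G, mask)
        return G, X, report.as_dict()
    seed = derive_seed(cfg["seed"], "genotypes")
    G = simulate_genotypes(pool_spec_from_config(cfg, seed), g["n_individuals"])
    return G, G.dosages.astype(float), None


def fit_model(method: str, y_trn, X, trn, tst, mcmc: MCMCConfig):
    """Fit one model on the training rows of X and predict the test rows.

    GBLUP goes through the GRM form (eigen-sampler, O(n) per iteration);
    Bayes A and Spike-Slab regress on markers explicitly.
    Returns (samples, fitted training linear predictor, test predictions).
    """
    if method == "gblup":
        grm = compute_grm(X)
        grm_trn = type(grm)(
            values=grm.submatrix(trn),
            denominator=grm.denominator,
            individual_ids=grm.individual_ids[trn],
            source_loci=grm.source_loci,
        )
        samples = fit_gblup(y_trn, grm_trn, mcmc=mcmc)
        pred = predict(samples, grm.submatrix(tst, trn)) if len(tst) else np.empty(0)
    elif method == "bayes_a":
        samples = fit_bayes_a(y_trn, X[trn], mcmc=mcmc)
        pred = predict(samples, X[tst]) if len(tst) else np.empty(0)
    elif method == "spike_slab":
        samples = fit_spike_slab(y_trn, X[trn], mcmc=mcmc)
        pred = predict(samples, X[tst]) if len(tst) else np.empty(0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return samples, samples.linpred_mean, pred


def run_scenario_grid(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Execute the full scenario x method x data-used x replicate grid.

    Writes ResultRecords (records.csv), aggregate tables (aggregate.csv),
    per-scenario pairwise method comparisons (comparisons.csv), the QC report
    when a real panel is used, and a JSON manifest with all derived seeds.
    """
    cfg = (load_config(None, overrides=config) if isinstance(config, dict)
           else load_config(config))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = cfg["seed"]

    stage = "genotypes"
    try:
        G, X_full, qc_report = _load_panel(cfg)
        stage = "partition"
        from .trait_sim import partition_markers_qtl

        marker_idx, pool_idx = partition_markers_qtl(
            G, cfg["panel"]["n_markers"], derive_seed(master, "partition")
        )
        stage = "splits"
        grm_markers = compute_grm(X_full[:, marker_idx])
        plans = make_splits(
            G.n_individuals,
            cfg["validation"]["n_candidates"],
            cfg["replicates"],
            grm_markers,
            threshold=cfg["validation"].get("threshold", 0.125),
            seed=derive_seed(master, "splits"),
        )

        records = []
        seeds_used = {"genotypes": derive_seed(master, "genotypes"),
                      "partition": derive_seed(master, "partition"),
                      "splits": derive_seed(master, "splits"),
                      "trait": {}, "fit": {}}
        for si, scheme in enumerate(cfg["schemes"]):
            for ai, arch_cfg in enumerate(cfg["architectures"]):
                arch = ArchitectureSpec(
                    n_large=arch_cfg["n_large"],
                    pve_large=arch_cfg["pve_large"],
                    target_h2=cfg["target_h2"],
                    residual_variance=cfg["residual_variance"],
                )
                scenario = f"{scheme}_p{arch.n_large}_pve{arch.pve_large:g}"
                for plan in plans:
                    stage = f"trait {scenario} rep{plan.replicate_id}"
                    t_seed = derive_seed(master, "trait", si, ai, plan.replicate_id)
                    seeds_used["trait"][f"{scenario}/rep{plan.replicate_id}"] = t_seed
                    qtl, trait = simulate_scenario_trait(
                        G, pool_idx, scheme, cfg["panel"]["n_qtl"], arch, t_seed
                    )
                    loci_sets = {
                        "markers": marker_idx,
                        "markers_qtl": np.sort(
                            np.concatenate([marker_idx, qtl.qtl_indices])
                        ),
                        "qtl": qtl.qtl_indices,
                    }
                    trn = plan.trn_indices
                    tst = plan.tst_retained_indices
                    y = trait.phenotypes
                    for di, data_used in enumerate(cfg["data_used"]):
                        for mi, method in enumerate(cfg["methods"]):
                            stage = (f"fit {scenario} rep{plan.replicate_id} "
                                     f"{data_used} {method}")
                            f_seed = derive_seed(
                                master, "fit", si, ai, plan.replicate_id, di, mi
                            )
                            mcmc = mcmc_from_config(cfg, f_seed)
                            samples, fitted, pred = fit_model(
                                method, y[trn], X_full[:, loci_sets[data_used]],
                                trn, tst, mcmc,
                            )
                            test_corr = (
                                accuracy(y[tst], pred) if tst.size >= 3 else np.nan
                            )
                            records.append(
                                {
                                    "scenario": scenario,
                                    "scheme": scheme,
                                    "n_large": arch.n_large,
                                    "pve_large": arch.pve_large,
                                    "data_used": data_used,
                                    "method": method,
                                    "replicate_id": plan.replicate_id,
                                    "h2_estimate": estimate_h2(samples).posterior_mean,
                                    "train_r2": training_r2(y[trn], fitted),
                                    "test_correlation": test_corr,
                                    "realized_h2": trait.realized_h2,
                                    "realized_pve": trait.realized_pve,
                                    "n_tst_retained": int(tst.size),
                                    "fit_seed": f_seed,
                                }
                            )
    except Exception as err:
        raise RuntimeError(f"scenario grid failed at stage [{stage}]: {err}") from err

    records = pd.DataFrame(records)
    records.to_csv(out_dir / "records.csv", index=False)
    aggregate(records).to_csv(out_dir / "aggregate.csv", index=False)
    comparisons = []
    for (scenario, data_used), group in records.groupby(["scenario", "data_used"]):
        if group["method"].nunique() < 2 or group["test_correlation"].isna().any():
            continue
        comp = pairwise_method_comparison(group)
        comp.insert(0, "scenario", scenario)
        comp.insert(1, "data_used", data_used)
        comparisons.append(comp)
    if comparisons:
        pd.concat(comparisons).to_csv(out_dir / "comparisons.csv", index=False)
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": cfg,
        "seeds": seeds_used,
    }
    if qc_report is not None:
        manifest["qc_report"] = qc_report
        with open(out_dir / "qc_report.json", "w") as fh:
            json.dump(qc_report, fh, indent=2)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out_dir


def save_fit(samples, out_dir: str | Path) -> Path:
    """Serialize a model fit: CSV per parameter block + JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chains = {"mu": samples.mu, "sigma_e2": samples.sigma_e2, "var_g": samples.var_g}
    for name in ("sigma_g2", "sigma_beta2", "S0", "pi", "sigma_alpha2", "sigma_gamma2"):
        val = getattr(samples, name)
        if val is not None:
            chains[name] = val
    pd.DataFrame(chains).to_csv(out_dir / "chains.csv", index=False)
    if samples.beta_mean is not None:
        eff = {"beta_mean": samples.beta_mean}
        if samples.pip is not None:
            eff["pip"] = samples.pip
        pd.DataFrame(eff).to_csv(out_dir / "effects.csv", index=False)
    pd.DataFrame(
        {"u_mean": samples.u_mean, "linpred_mean": samples.linpred_mean}
    ).to_csv(out_dir / "genetic_values.csv", index=False)
    manifest = {
        "model": samples.model,
        "form": samples.form,
        "n_draws": samples.n_draws,
        "mcmc": {
            "n_iter": samples.config.n_iter,
            "burn_in": samples.config.burn_in,
            "thin": samples.config.thin,
            "seed": samples.config.seed,
        },
        "ess": samples.ess(),
        "h2": estimate_h2(samples).posterior_mean,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out_dir
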