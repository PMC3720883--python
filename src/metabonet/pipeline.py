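"""End-to-end orchestration of the covariance-network analysis.

Stage order mirrors the analysis design: cohort (synthesized or loaded) ->
reference normalization -> education screen -> confound regression ->
regional group t-tests -> per-group connectivity + bootstraps -> edge-wise
matrix comparisons -> attribute curves / AUC / KW -> NBC profile + hubs ->
lobe and Core covariation analyses.  A single root seed deterministically
spawns per-stage seeds, so (config, seed) fully determines every
stochastic output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import lobes as lobes_mod
from .atlas import CohortTable, RegionAtlas, load_atlas, load_cohort, write_cohort
from .connectivity import (
    BootstrapConfig,
    bootstrap_matrices,
    compare_matrices,
    edge_involvement_counts,
    pearson_matrix,
    sparsity_grid,
)
from .group_stats import METRICS, attribute_curves, compare_auc, nbc_profile, select_hubs
from .preprocess import (
    DEFAULT_CONTRASTS,
    normalize_reference,
    regional_group_ttests,
    remove_confounds,
    screen_covariate,
)
from .synth import CohortSpec, generate_cohort

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    atlas: str = "aal90"
    cohort_path: str | None = None  # mutually exclusive with cohort_spec
    cohort_spec: CohortSpec | None = None
    n_boot: int = 300
    bootstrap_fraction: float = 0.8
    sparsity_start: float = 0.5
    sparsity_stop: float = 0.9
    sparsity_step: float = 0.02
    metrics: tuple[str, ...] = ("C", "L", "Eglob", "Eloc", "sigma")
    sigma_n_null: int = 20
    q: float = 0.05
    alpha: float = 0.05
    hub_threshold: float = 1.5
    top_k: int = 1000
    normalize_ref: bool = True
    seed: int = 0
    out_dir: str = "metabonet_run"

    def validate(self) -> None:
        unknown = set(self.metrics) - set(METRICS)
        if unknown:
            raise ValueError(f"unknown metric(s): {sorted(unknown)}")
        if self.cohort_path is None and self.cohort_spec is None:
            raise ValueError("config must provide cohort_path or cohort_spec")
        if self.cohort_path is not None and not Path(self.cohort_path).exists():
            raise ValueError(f"cohort file not found: {self.cohort_path}")

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        blob = json.dumps(_to_jsonable(d), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        spec = raw.pop("cohort_spec", None)
        cfg = cls(**raw)
        if spec is not None:
            cfg.cohort_spec = cohort_spec_from_dict(spec)
        return cfg


def cohort_spec_from_dict(d: dict) -> CohortSpec:
    from .synth import CovariateEffects

    d = dict(d)
    if "covariate_effects" in d:
        d["covariate_effects"] = CovariateEffects(**d["covariate_effects"])
    if "hypometabolic_regions" in d:
        d["hypometabolic_regions"] = {
            g: (tuple(v[0]), float(v[1])) for g, v in d["hypometabolic_regions"].items()
        }
    return CohortSpec(**d)


def _to_jsonable(x):
    if isinstance(x, dict):
        return {str(k): _to_jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_to_jsonable(v) for v in x]
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, (np.bool_,)):
        return bool(x)
    return x


def _stage_seed(root_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _provenance_header(config: RunConfig, stage: str) -> str:
    return f"# metabonet stage={stage} seed={config.seed} config={config.config_hash()}\n"


def _write_csv(df, path: Path, config: RunConfig, stage: str) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(config, stage))
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the machine-readable summary.

    Artifacts (CSV tables and a ``summary.json``) are written under
    ``config.out_dir``; a failing stage leaves earlier outputs intact.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = load_atlas(config.atlas)
    summary: dict = {"seed": config.seed, "config_hash": config.config_hash(), "stages": []}

    # --- cohort -----------------------------------------------------------
    log.info("stage: cohort")
    if config.cohort_path:
        cohort = load_cohort(config.cohort_path, atlas)
    else:
        spec = dataclasses.replace(
            config.cohort_spec, seed=_stage_seed(config.seed, "synth")
        )
        cohort = generate_cohort(spec, atlas)
        write_cohort(cohort, out / "cohort.tsv")
    summary["n_subjects"] = cohort.n_subjects
    summary["groups"] = {g: int((cohort.group == g).sum()) for g in sorted(set(cohort.group))}
    summary["stages"].append("cohort")

    # --- preprocessing ----------------------------------------------------
    log.info("stage: preprocess")
    if config.normalize_ref:
        cohort = normalize_reference(cohort)
    screen = screen_covariate(cohort, "education", alpha=config.alpha)
    summary["education_kept"] = bool(screen.keep)
    ttests = regional_group_ttests(
        cohort, DEFAULT_CONTRASTS, alpha=config.alpha, education=screen.keep
    )
    _write_csv(ttests.table, out / "regional_ttests.csv", config, "preprocess")
    hypo_sets = {
        f"{a}_vs_{b}": ttests.significant((a, b)) for a, b in DEFAULT_CONTRASTS
    }
    summary["hypometabolic_regions"] = {k: len(v) for k, v in hypo_sets.items()}
    summary["stages"].append("preprocess")

    # --- connectivity -----------------------------------------------------
    log.info("stage: connectivity")
    groups = sorted(set(cohort.group), key=["NC", "MCI", "AD"].index)
    residuals_by_group: dict[str, np.ndarray] = {}
    full_matrices = {}
    boot_matrices = {}
    for g in groups:
        sub = cohort.group_table(g)
        res = remove_confounds(sub, education=screen.keep)
        residuals_by_group[g] = res.values
        full_matrices[g] = pearson_matrix(res.values, atlas)
        bc = BootstrapConfig(
            n_boot=config.n_boot,
            fraction=config.bootstrap_fraction,
            seed=_stage_seed(config.seed, f"bootstrap:{g}"),
        )
        boot_matrices[g] = bootstrap_matrices(res.values, bc, atlas)
    grid = sparsity_grid(config.sparsity_start, config.sparsity_stop, config.sparsity_step)
    summary["sparsity_grid"] = grid.tolist()
    summary["stages"].append("connectivity")

    # --- edge-wise matrix comparisons -------------------------------------
    log.info("stage: edge comparisons")
    summary["edge_differences"] = {}
    for a, b in DEFAULT_CONTRASTS:
        if a not in full_matrices or b not in full_matrices:
            continue
        comp = compare_matrices(full_matrices[a], full_matrices[b], atlas, q=config.q)
        _write_csv(comp, out / f"edge_comparison_{a}_vs_{b}.csv", config, "edges")
        counts = edge_involvement_counts(comp, atlas)
        counts.rename("significant_edges").to_frame().to_csv(
            out / f"edge_involvement_{a}_vs_{b}.csv"
        )
        summary["edge_differences"][f"{a}_vs_{b}"] = int(comp["significant"].sum())
    summary["stages"].append("edges")

    # --- attribute curves + AUC KW ----------------------------------------
    log.info("stage: attribute curves")
    import pandas as pd

    auc_rows = []
    summary["auc_kw"] = {}
    for metric in config.metrics:
        aucs = {}
        for g in groups:
            curve = attribute_curves(
                boot_matrices[g],
                grid,
                metric,
                sigma_n_null=config.sigma_n_null,
                sigma_seed=_stage_seed(config.seed, f"sigma:{g}:{metric}"),
            )
            aucs[g] = curve.auc()
            for b, v in enumerate(aucs[g]):
                auc_rows.append(dict(metric=metric, group=g, bootstrap=b, auc=v))
        kw = compare_auc(aucs, alpha=config.alpha)
        summary["auc_kw"][metric] = {
            "statistic": kw.statistic,
            "p": kw.p,
            "group_means": {g: float(np.mean(aucs[g])) for g in groups},
            "post_hoc": _to_jsonable(kw.post_hoc.to_dict("records")),
        }
    _write_csv(pd.DataFrame(auc_rows), out / "attribute_auc.csv", config, "attributes")
    summary["stages"].append("attributes")

    # --- NBC profile + hubs -----------------------------------------------
    log.info("stage: NBC")
    profile = nbc_profile(boot_matrices, grid, atlas, alpha=config.alpha)
    nbc_df = profile.mean_nbc.copy()
    nbc_df.insert(0, "region", nbc_df.index)
    nbc_df["significant_fraction"] = profile.significant_fraction
    nbc_df["flagged"] = profile.flagged
    _write_csv(nbc_df.reset_index(drop=True), out / "nbc_profile.csv", config, "nbc")
    hubs = select_hubs(profile, threshold=config.hub_threshold)
    _write_csv(hubs, out / "hubs.csv", config, "nbc")
    summary["nbc_upper_bound"] = profile.upper_bound
    summary["nbc_flagged_regions"] = [
        atlas.abbreviations[i] for i in np.flatnonzero(profile.flagged)
    ]
    summary["hubs"] = {
        g: hubs.loc[hubs["group"] == g, "region"].tolist() for g in groups
    }
    summary["stages"].append("nbc")

    # --- lobe / Core analyses ---------------------------------------------
    log.info("stage: lobes")
    lobe_report = lobes_mod.lobe_covariation_report(
        boot_matrices, atlas, top_k=config.top_k, alpha=config.alpha
    )
    _write_csv(lobe_report, out / "lobe_covariation.csv", config, "lobes")
    core = lobes_mod.core_analysis(boot_matrices, atlas, alpha=config.alpha)
    summary["core"] = {
        name: {
            "kw_p": kw.p,
            "group_means": {g: float(np.mean(s)) for g, s in samples.items()},
        }
        for name, (samples, kw) in core.items()
    }
    ad_set = hypo_sets.get("NC_vs_AD", [])
    if len(ad_set) >= 2:
        samples, kw = lobes_mod.hypometabolic_set_covariation(
            boot_matrices, atlas.indices_of(ad_set), alpha=config.alpha
        )
        summary["hypometabolic_covariation"] = {
            "regions": ad_set,
            "kw_p": kw.p,
            "group_means": {g: float(np.mean(s)) for g, s in samples.items()},
        }
    summary["stages"].append("lobes")

    (out / "summary.json").write_text(json.dumps(_to_jsonable(summary), indent=2, sort_keys=True))
    return summary
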