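"""End-to-end orchestration of the host-microbe interaction workflow.

``run_pipeline`` executes, from three input tables (genes, taxa, metadata,
plus optional cell-type scores):

1. load + sample alignment
2. CLR transform, Shannon diversity, Aitchison distances, dysbiosis scoring
3. residualization of genes and CLR taxa against the confounders
4. sparse CCA per stratum (default: inflammation) with LOO significance
5. pairwise gene-taxon association scan
6. phenotype-conditional network build + per-taxon shift tests
7. dysbiosis interaction scan + permutation false-positive estimate
8. lasso variance partitioning of cell-type scores

Every intermediate is written as TSV under the output directory and a JSON
manifest records the stage list, feature/sample counts, seed and a hash of
the configuration; under a fixed seed the output files are byte-identical
across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .compositional import aitchison_distance, clr_transform, dysbiosis_score, shannon_index
from .containers import OmicsMatrix, SampleMetadata
from .io import align_samples, load_matrix, load_metadata
from .linmod import association_scan, interaction_scan, permutation_fpr, residualize
from .network import build_network, compare_taxon_clusters
from .scca import CcaPenalty, loo_significance, tune_penalties
from .varpart import partition_variance

logger = logging.getLogger("mucolink.pipeline")

__all__ = ["PipelineConfig", "run_pipeline"]

DEFAULT_COVARIATES = (
    "inflammation",
    "location",
    "age",
    "sex",
    "bmi",
    "med_aminosalicylates",
    "med_thiopurines",
    "med_steroids",
    "batch",
)
# residualization covariates for sparse CCA: confounders, not the random batch
RESIDUAL_COVARIATES = DEFAULT_COVARIATES


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (TOML-loadable)."""

    gene_path: str = ""
    taxa_path: str = ""
    meta_path: str = ""
    cell_path: Optional[str] = None
    out_dir: str = "mucolink_out"
    covariates: Sequence[str] = DEFAULT_COVARIATES
    patient_col: str = "patient"
    control_col: str = "diagnosis"
    control_value: str = "nonIBD"
    phenotype_col: str = "phenotype"
    stratify_col: str = "inflammation"
    pseudocount: float = 0.5
    dysbiosis_quantile: float = 0.9
    lambda1: Optional[float] = None
    lambda2: Optional[float] = None
    tune_grid: Optional[Sequence[float]] = None
    n_components: int = 10
    alpha_assoc: float = 0.05
    alpha_component: float = 0.1
    n_permutations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name, a in (("alpha_assoc", self.alpha_assoc), ("alpha_component", self.alpha_component)):
            if not (0.0 < a < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if not (0.0 < self.dysbiosis_quantile < 1.0):
            raise ValueError("dysbiosis_quantile must lie in (0, 1)")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = {k: (list(v) if isinstance(v, (tuple, list)) else v) for k, v in dataclasses.asdict(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _stage_seed(root: int, offset: int) -> int:
    return (root * 1009 + offset) % (2**31 - 1)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": [],
    }

    def record(stage: str, **info) -> None:
        logger.info("stage %s: %s", stage, info)
        manifest["stages"].append({"name": stage, **info})

    def _fail(stage: str, err: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    # 1 -- load ------------------------------------------------------------
    stage = "load"
    try:
        genes = load_matrix(config.gene_path, kind="gene", unit="log")
        taxa = load_matrix(config.taxa_path, kind="taxon", unit="counts")
        meta = load_metadata(config.meta_path, patient_col=config.patient_col)
        cells = load_matrix(config.cell_path, kind="celltype", unit="score") if config.cell_path else None
        tables = [genes, taxa, meta] + ([cells] if cells is not None else [])
        aligned = align_samples(*tables)
        genes, taxa, meta = aligned[0], aligned[1], aligned[2]
        cells = aligned[3] if cells is not None else None
        meta.require([config.control_col, config.phenotype_col, *config.covariates])
    except Exception as err:  # noqa: BLE001 - every stage reports its name
        _fail(stage, err)
    record(stage, n_samples=genes.n_samples, n_genes=genes.n_features, n_taxa=taxa.n_features)

    # 2 -- compositional ---------------------------------------------------
    stage = "compositional"
    try:
        clr = clr_transform(taxa, pseudocount=config.pseudocount)
        shannon = shannon_index(taxa)
        dist = aitchison_distance(clr)
        controls = meta.data.index[meta.data[config.control_col] == config.control_value].tolist()
        dys = dysbiosis_score(clr, controls, quantile=config.dysbiosis_quantile)
        clr.values.to_csv(out / "taxa_clr.tsv", sep="\t")
        shannon.to_csv(out / "shannon.tsv", sep="\t")
        dist.to_csv(out / "aitchison_distance.tsv", sep="\t")
        pd.DataFrame({"score": dys.score, "status": dys.status}).to_csv(out / "dysbiosis.tsv", sep="\t")
    except Exception as err:
        _fail(stage, err)
    record(stage, n_controls=len(controls), n_dysbiotic=int(dys.is_dysbiotic.sum()), threshold=dys.threshold)

    # 3 -- residualize -----------------------------------------------------
    stage = "residualize"
    try:
        clr_mx = OmicsMatrix(data=clr.values.T, kind="taxon", unit="clr")
        genes_res = residualize(genes, meta, list(config.covariates))
        taxa_res = residualize(clr_mx, meta, list(config.covariates))
        genes_res.data.to_csv(out / "genes_residual.tsv", sep="\t")
        taxa_res.data.to_csv(out / "taxa_residual.tsv", sep="\t")
    except Exception as err:
        _fail(stage, err)
    record(stage, n_genes=genes_res.n_features, n_taxa=taxa_res.n_features)

    # 4 -- sparse CCA per stratum -------------------------------------------
    stage = "scca"
    try:
        strata = sorted(meta.data[config.stratify_col].astype(str).unique())
        scca_info = {}
        for level in strata:
            ids = meta.data.index[meta.data[config.stratify_col].astype(str) == level].tolist()
            X = taxa_res.data[ids].T
            Y = genes_res.data[ids].T
            if config.lambda1 is not None and config.lambda2 is not None:
                pen = CcaPenalty(config.lambda1, config.lambda2)
            else:
                pen = tune_penalties(X, Y, grid=config.tune_grid, seed=_stage_seed(config.seed, 4))
            model = loo_significance(
                X, Y, pen, n_components=config.n_components, alpha=config.alpha_component
            )
            tag = f"{config.stratify_col}_{level}"
            model.loadings_table().to_csv(out / f"scca_loadings_{tag}.tsv", sep="\t", index=False)
            model.summary_table().to_csv(out / f"scca_summary_{tag}.tsv", sep="\t", index=False)
            scca_info[level] = {
                "lambda1": model.penalty.lambda1,
                "lambda2": model.penalty.lambda2,
                "n_kept": int(sum(bool(c.keep) for c in model.components)),
            }
    except Exception as err:
        _fail(stage, err)
    record(stage, strata=scca_info)

    # 5 -- association scan --------------------------------------------------
    stage = "associate"
    try:
        assoc = association_scan(genes, clr, meta, list(config.covariates))
        assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
    except Exception as err:
        _fail(stage, err)
    record(stage, n_pairs=len(assoc), n_significant=int((assoc["p_adj"] < config.alpha_assoc).sum()))

    # 6 -- phenotype networks + shift tests ----------------------------------
    stage = "network"
    try:
        ph = meta.data[config.phenotype_col].astype(str)
        levels = sorted(ph.unique())
        if len(levels) != 2:
            raise ValueError(f"phenotype column must be binary, got levels {levels}")
        per_group = {}
        for level in levels:
            ids = meta.data.index[ph == level].tolist()
            tab = association_scan(
                genes.subset_samples(ids),
                OmicsMatrix(data=clr.values.loc[ids].T, kind="taxon", unit="clr"),
                meta.subset(ids),
                list(config.covariates),
            )
            tab.to_csv(out / f"associations_{config.phenotype_col}_{level}.tsv", sep="\t", index=False)
            net = build_network(tab, alpha=config.alpha_assoc, group_label=level)
            net.edge_table().to_csv(out / f"network_{config.phenotype_col}_{level}.tsv", sep="\t", index=False)
            per_group[level] = tab
        shifts = compare_taxon_clusters(
            per_group[levels[0]], per_group[levels[1]], background=list(genes.features), alpha=config.alpha_assoc
        )
        shifts.to_csv(out / "network_shifts.tsv", sep="\t", index=False)
    except Exception as err:
        _fail(stage, err)
    record(
        stage,
        groups=levels,
        n_shift_tested=len(shifts),
        n_shift_significant=int((shifts["p_adj"] < config.alpha_assoc).sum()) if len(shifts) else 0,
    )

    # 7 -- dysbiosis interactions --------------------------------------------
    stage = "interactions"
    try:
        inter = interaction_scan(genes, clr, dys, meta, list(config.covariates))
        inter.to_csv(out / "interactions.tsv", sep="\t", index=False)
        perm = permutation_fpr(
            genes,
            clr,
            dys,
            meta,
            list(config.covariates),
            n_rounds=config.n_permutations,
            alpha=config.alpha_assoc,
            seed=_stage_seed(config.seed, 7),
        )
        pd.DataFrame({"round": range(1, perm.n_rounds + 1), "sig_count": perm.sig_counts}).to_csv(
            out / "permutation_fpr.tsv", sep="\t", index=False
        )
    except Exception as err:
        _fail(stage, err)
    record(
        stage,
        n_pairs=len(inter),
        n_significant=int((inter["p_adj"] < config.alpha_assoc).sum()),
        permutation_fpr=perm.fpr_estimate,
    )

    # 8 -- variance partitioning ---------------------------------------------
    stage = "varpart"
    try:
        if cells is not None:
            summary, contrib = partition_variance(cells, meta, clr, seed=_stage_seed(config.seed, 8))
            summary.to_csv(out / "varpart_summary.tsv", sep="\t", index=False)
            contrib.to_csv(out / "varpart_contributors.tsv", sep="\t", index=False)
            info = {"n_celltypes": cells.n_features}
        else:
            info = {"skipped": "no cell-type score table supplied"}
    except Exception as err:
        _fail(stage, err)
    record(stage, **info)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
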