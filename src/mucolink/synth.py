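"""Synthetic paired gene/taxa cohorts with planted ground truth.

The generator emulates a mucosal biopsy cohort: several biopsies per patient,
zero-inflated compositional taxon counts, continuous log-scale gene
expression, and the covariate structure of the association models
(inflammation, location, age, sex, BMI, three medication flags, batch).
Structure is planted so every downstream stage has a recovery oracle:

* **modules** — latent Gaussian factors shared by a block of taxa (loading 1)
  and a block of genes (loading ``module_strength``), giving correlated
  gene-taxa blocks for sparse CCA and the pairwise association scan;
* **dysbiosis** — a fraction of non-control samples is displaced by a fixed
  vector in latent (CLR-like) space, so the median-distance dysbiosis score
  can separate them;
* **interaction pairs** — gene-taxon pairs whose slope flips sign between
  eubiotic and dysbiotic samples, the target of the interaction scan;
* **group edges** — taxon-gene associations whose slope differs between two
  patient phenotype groups, the target of the network-shift test;
* **cell-type scores** — optional synthetic enrichment scores generated from
  a handful of taxa at a controlled R-squared, the variance-partition oracle.

Taxon counts arise as latent Gaussians -> softmax composition -> multinomial
draw at a Poisson library size, with structural zeros knocked out before
renormalization, which reproduces the compositional, zero-inflated sampling
the CLR stage must absorb. Gene values are emitted directly on the log scale.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .compositional import clr_transform
from .containers import OmicsMatrix, SampleMetadata

__all__ = ["SynthConfig", "GroundTruth", "Cohort", "generate_cohort", "generate_null_cohort", "write_fixture"]

_DEFAULT_CONFOUNDERS: Mapping[str, float] = {
    "age": 0.1,
    "sex": 0.2,
    "bmi": 0.1,
    "inflammation": 0.5,
    "location": 0.5,
    "medication": 0.2,
    "batch": 0.2,
}

MEDICATION_FLAGS = ("med_aminosalicylates", "med_thiopurines", "med_steroids")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic cohort.

    Effect sizes in ``confounder_effects`` are standard deviations of random
    per-feature coefficients on standardized covariates, applied on the
    log/CLR scale.
    """

    n_patients: int = 150
    biopsies_per_patient: int = 2
    n_genes: int = 300
    n_taxa: int = 50
    n_modules: int = 2
    module_gene_size: int = 20
    module_taxon_size: int = 5
    module_strength: float = 0.8
    patient_effect_sd: float = 0.5
    noise_sd: float = 0.5
    zero_inflation: float = 0.1
    library_size_mean: float = 20000.0
    confounder_effects: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_CONFOUNDERS))
    n_control_patients: int = 0
    frac_dysbiotic: float = 0.1
    dysbiosis_shift: float = 14.0
    interaction_pairs: int = 0
    interaction_slope: float = 1.0
    group_specific_edges: tuple[int, int] = (0, 0)
    edge_strength: float = 1.0
    edge_mode: str = "flip"  # "flip": slope negated in the other group; "presence": slope 0 there
    de_genes: int = 0
    de_effect: float = 1.0
    n_celltypes: int = 0
    celltype_taxa: int = 5
    celltype_r2: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_patients": self.n_patients,
            "biopsies_per_patient": self.biopsies_per_patient,
            "n_genes": self.n_genes,
            "n_taxa": self.n_taxa,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be a positive count (got {v})")
        for name in ("n_modules", "interaction_pairs", "n_control_patients", "de_genes", "n_celltypes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_modules > 0:
            if self.module_gene_size < 1 or self.module_taxon_size < 1:
                raise ValueError("module sizes must be positive")
            if self.n_modules * self.module_gene_size > self.n_genes:
                raise ValueError("planted module genes exceed n_genes")
            if self.n_modules * self.module_taxon_size > self.n_taxa:
                raise ValueError("planted module taxa exceed n_taxa")
            if not (0.0 <= self.module_strength <= 1.0):
                raise ValueError("module_strength must lie in [0, 1]")
        for name in ("zero_inflation", "frac_dysbiotic"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1] (got {v})")
        for name in ("patient_effect_sd", "noise_sd", "dysbiosis_shift", "edge_strength"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.library_size_mean <= 0:
            raise ValueError("library_size_mean must be positive")
        if self.edge_mode not in ("flip", "presence"):
            raise ValueError("edge_mode must be 'flip' or 'presence'")
        if len(self.group_specific_edges) != 2 or any(v < 0 for v in self.group_specific_edges):
            raise ValueError("group_specific_edges must be two nonnegative counts")
        if self.n_celltypes > 0:
            if not (0.0 < self.celltype_r2 < 1.0):
                raise ValueError("celltype_r2 must lie in (0, 1)")
            if not (1 <= self.celltype_taxa <= self.n_taxa):
                raise ValueError("celltype_taxa must lie in [1, n_taxa]")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort; the recovery oracle for tests."""

    module_members: list = field(default_factory=list)  # [{"genes": [...], "taxa": [...]}]
    interaction_truth: list = field(default_factory=list)  # [{"gene","taxon","slope_eubiotic","slope_dysbiotic"}]
    group_edges: dict = field(default_factory=dict)  # group -> [(taxon, gene, slope)]
    dysbiotic_samples: list = field(default_factory=list)
    variance_truth: dict = field(default_factory=dict)  # celltype -> {"bacteria": r2, "taxa": [...]}
    de_genes: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["group_edges"] = {g: [tuple(e) for e in edges] for g, edges in d.get("group_edges", {}).items()}
        return cls(**d)

    def validate_ids(self, genes: OmicsMatrix, taxa: OmicsMatrix, meta: SampleMetadata) -> None:
        gene_ids = set(genes.features)
        taxa_ids = set(taxa.features)
        sample_ids = set(meta.samples)
        for m in self.module_members:
            assert set(m["genes"]) <= gene_ids and set(m["taxa"]) <= taxa_ids
        for it in self.interaction_truth:
            assert it["gene"] in gene_ids and it["taxon"] in taxa_ids
        for edges in self.group_edges.values():
            for taxon, gene, _ in edges:
                assert gene in gene_ids and taxon in taxa_ids
        assert set(self.dysbiotic_samples) <= sample_ids


@dataclass
class Cohort:
    """Bundle returned by the generator.

    Iterating yields the 4-tuple ``(genes, taxa, meta, truth)``; synthetic
    cell-type scores, when requested, ride along as ``cells``.
    """

    genes: OmicsMatrix
    taxa: OmicsMatrix
    meta: SampleMetadata
    truth: GroundTruth
    cells: Optional[OmicsMatrix] = None

    def __iter__(self):
        return iter((self.genes, self.taxa, self.meta, self.truth))


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def generate_cohort(config: SynthConfig) -> Cohort:
    """Generate one paired cohort with all planted structure of ``config``.

    Deterministic: identical configs (including seed) yield bit-identical
    outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_ibd = config.n_patients
    n_ctl = config.n_control_patients
    n_pat = n_ibd + n_ctl
    bpp = config.biopsies_per_patient
    n = n_pat * bpp
    patients = [f"P{i + 1:04d}" for i in range(n_pat)]
    is_control_pat = np.array([i >= n_ibd for i in range(n_pat)])
    samples = [f"S{i + 1:05d}" for i in range(n)]
    pat_of_sample = np.repeat(np.arange(n_pat), bpp)

    gene_ids = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    taxa_ids = [f"T{i + 1:03d}" for i in range(config.n_taxa)]

    # --- covariates -------------------------------------------------------
    age_pat = rng.uniform(18, 80, n_pat)
    sex_pat = rng.integers(0, 2, n_pat)  # 0 = F, 1 = M
    bmi_pat = rng.normal(25, 4, n_pat)
    med_pat = rng.binomial(1, 0.3, size=(n_pat, 3))
    pheno_pat = rng.integers(0, 2, n_pat)  # phenotype group A/B
    inflammation = rng.binomial(1, 0.4, n)
    location = rng.integers(0, 2, n)  # 0 = colon, 1 = ileum
    batch = rng.integers(0, 4, n)

    meta_df = pd.DataFrame(
        {
            "patient": [patients[i] for i in pat_of_sample],
            "diagnosis": np.where(is_control_pat[pat_of_sample], "nonIBD", "IBD"),
            "inflammation": inflammation,
            "location": np.where(location == 1, "ileum", "colon"),
            "age": age_pat[pat_of_sample],
            "sex": np.where(sex_pat[pat_of_sample] == 1, "M", "F"),
            "bmi": bmi_pat[pat_of_sample],
            "med_aminosalicylates": med_pat[pat_of_sample, 0],
            "med_thiopurines": med_pat[pat_of_sample, 1],
            "med_steroids": med_pat[pat_of_sample, 2],
            "batch": [f"B{b + 1}" for b in batch],
            "phenotype": np.where(pheno_pat[pat_of_sample] == 1, "B", "A"),
        },
        index=pd.Index(samples, name="sample"),
    )

    # numeric covariate columns used for planted linear effects
    cov_cols = {
        "age": _standardize(meta_df["age"].to_numpy()),
        "sex": (meta_df["sex"] == "M").to_numpy(dtype=float),
        "bmi": _standardize(meta_df["bmi"].to_numpy()),
        "inflammation": meta_df["inflammation"].to_numpy(dtype=float),
        "location": (meta_df["location"] == "ileum").to_numpy(dtype=float),
    }
    med_block = meta_df[list(MEDICATION_FLAGS)].to_numpy(dtype=float)
    batch_block = np.stack([(batch == b).astype(float) for b in range(1, 4)], axis=1)

    def confounder_effect(n_features: int) -> np.ndarray:
        """Random per-feature linear covariate effects on the latent scale."""
        eff = np.zeros((n, n_features))
        ce = config.confounder_effects
        for name, col in cov_cols.items():
            sd = ce.get(name, 0.0)
            if sd > 0:
                eff += np.outer(col, rng.normal(0.0, sd, n_features))
        sd = ce.get("medication", 0.0)
        if sd > 0:
            eff += med_block @ rng.normal(0.0, sd, (3, n_features))
        sd = ce.get("batch", 0.0)
        if sd > 0:
            eff += batch_block @ rng.normal(0.0, sd, (3, n_features))
        return eff

    # --- planted modules --------------------------------------------------
    factors = rng.standard_normal((n, config.n_modules)) if config.n_modules else np.zeros((n, 0))
    module_members = []
    for m in range(config.n_modules):
        g0 = m * config.module_gene_size
        t0 = m * config.module_taxon_size
        module_members.append(
            {
                "genes": gene_ids[g0 : g0 + config.module_gene_size],
                "taxa": taxa_ids[t0 : t0 + config.module_taxon_size],
            }
        )

    # --- dysbiotic samples ------------------------------------------------
    ibd_samples = np.where(~is_control_pat[pat_of_sample])[0]
    n_dys = int(round(config.frac_dysbiotic * ibd_samples.size))
    dys_idx = rng.choice(ibd_samples, size=n_dys, replace=False) if n_dys else np.array([], dtype=int)
    dys_mask = np.zeros(n, dtype=bool)
    dys_mask[dys_idx] = True
    # The community displacement spans the non-planted taxa: planted module /
    # interaction / hub taxa take part through their gene associations, not
    # as drivers of the dysbiosis shift itself. A shift of tens of CLR units
    # concentrated on a planted taxon would push it below detection in
    # dysbiotic samples and destroy the within-stratum variation every
    # interaction model needs.
    shift_dir = rng.standard_normal(config.n_taxa)
    n_mod_taxa_ = config.n_modules * config.module_taxon_size
    n_special_ = n_mod_taxa_ + config.interaction_pairs + sum(
        1 for e in config.group_specific_edges if e > 0
    )
    if 0 < n_special_ < config.n_taxa:
        shift_dir[:n_special_] = 0.0
    norm = np.linalg.norm(shift_dir)
    shift_dir = shift_dir / norm if norm > 0 else shift_dir

    # --- taxa: latent Gaussian -> softmax -> multinomial ------------------
    # Planted-module taxa get moderately common baselines (N(1, 1) vs N(0, 2)
    # for the rest): detectable host-microbe modules involve prevalent
    # genera, and CLR values of rare, dropout-ridden taxa are mostly noise.
    taxa_baseline = rng.normal(0.0, 2.0, config.n_taxa)
    n_mod_taxa = config.n_modules * config.module_taxon_size
    n_hub_taxa = sum(1 for e in config.group_specific_edges if e > 0)
    n_special = n_mod_taxa + config.interaction_pairs + n_hub_taxa
    if n_special:
        taxa_baseline[:n_special] = rng.normal(1.0, 1.0, min(n_special, config.n_taxa))
    L = np.tile(taxa_baseline, (n, 1))
    for m in range(config.n_modules):
        t0 = m * config.module_taxon_size
        L[:, t0 : t0 + config.module_taxon_size] += factors[:, [m]]
    L += confounder_effect(config.n_taxa)
    L += rng.normal(0.0, config.patient_effect_sd, (n_pat, config.n_taxa))[pat_of_sample]
    L += rng.normal(0.0, config.noise_sd, (n, config.n_taxa))

    # standardized pre-shift latents: the basis for planted gene effects, so
    # that planted associations reflect the taxon itself and not the common
    # dysbiosis displacement shared by all taxa
    z_latent = (L - L.mean(axis=0)) / np.where(L.std(axis=0) > 0, L.std(axis=0), 1.0)
    L[dys_mask] += config.dysbiosis_shift * shift_dir

    # Structural dropout is abundance-dependent, as in real sequencing data:
    # the probability that an entry is structurally zero falls logistically
    # with its latent abundance, so prevalent taxa are essentially never
    # zeroed while rare taxa often are. The global offset t0 is solved by
    # bisection so the marginal dropout rate equals ``zero_inflation``.
    if config.zero_inflation > 0:
        lo, hi = float(L.min()) - 10.0, float(L.max()) + 10.0
        for _ in range(80):
            t0 = 0.5 * (lo + hi)
            rate = float(np.mean(1.0 / (1.0 + np.exp(L - t0))))
            if rate < config.zero_inflation:
                lo = t0
            else:
                hi = t0
        p_zero = 1.0 / (1.0 + np.exp(L - t0))
        zero_mask = rng.random((n, config.n_taxa)) < p_zero
    else:
        zero_mask = np.zeros((n, config.n_taxa), dtype=bool)
    # keep at least 2 observable taxa per sample
    for i in np.where(zero_mask.sum(axis=1) > config.n_taxa - 2)[0]:
        keep = rng.choice(config.n_taxa, size=min(2, config.n_taxa), replace=False)
        zero_mask[i, keep] = False

    logits = np.where(zero_mask, -np.inf, L)
    logits -= logits.max(axis=1, keepdims=True)
    P = np.exp(logits)
    P /= P.sum(axis=1, keepdims=True)
    libsize = np.maximum(rng.poisson(config.library_size_mean, n), 1)
    counts = np.empty((n, config.n_taxa), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(libsize[i], P[i])

    # --- genes: log-scale continuous -------------------------------------
    G = np.tile(rng.normal(6.0, 1.0, config.n_genes), (n, 1))
    for m in range(config.n_modules):
        g0 = m * config.module_gene_size
        G[:, g0 : g0 + config.module_gene_size] += config.module_strength * factors[:, [m]]
    G += confounder_effect(config.n_genes)
    G += rng.normal(0.0, config.patient_effect_sd, (n_pat, config.n_genes))[pat_of_sample]
    G += rng.normal(0.0, config.noise_sd, (n, config.n_genes))

    in_module_genes = config.n_modules * config.module_gene_size
    in_module_taxa = config.n_modules * config.module_taxon_size
    free_genes = list(range(in_module_genes, config.n_genes))
    free_taxa = list(range(in_module_taxa, config.n_taxa))

    # --- planted inflammation DE genes ------------------------------------
    de_list = []
    if config.de_genes:
        if config.de_genes > len(free_genes):
            raise ValueError("de_genes exceeds genes left outside planted modules")
        chosen = [free_genes.pop(0) for _ in range(config.de_genes)]
        for gi in chosen:
            G[:, gi] += config.de_effect * cov_cols["inflammation"]
            de_list.append(gene_ids[gi])

    # --- dysbiosis sign-flip interaction pairs ----------------------------
    interaction_truth = []
    if config.interaction_pairs:
        if config.interaction_pairs > min(len(free_genes), len(free_taxa)):
            raise ValueError("interaction_pairs exceeds free genes/taxa outside modules")
        for _ in range(config.interaction_pairs):
            gi = free_genes.pop(0)
            tj = free_taxa.pop(0)
            z = z_latent[:, tj]
            s_eu, s_dy = config.interaction_slope, -config.interaction_slope
            G[:, gi] += np.where(dys_mask, s_dy, s_eu) * z
            interaction_truth.append(
                {
                    "gene": gene_ids[gi],
                    "taxon": taxa_ids[tj],
                    "slope_eubiotic": s_eu,
                    "slope_dysbiotic": s_dy,
                }
            )

    # --- phenotype-group-specific edges -----------------------------------
    group_edges: dict[str, list] = {"A": [], "B": []}
    n_edges_a, n_edges_b = config.group_specific_edges
    in_a = (meta_df["phenotype"] == "A").to_numpy()
    for group, n_edges in (("A", n_edges_a), ("B", n_edges_b)):
        if n_edges == 0:
            continue
        if not free_taxa or n_edges > len(free_genes):
            raise ValueError("not enough free genes/taxa for group-specific edges")
        tj = free_taxa.pop(0)  # one hub taxon per group
        here = in_a if group == "A" else ~in_a
        z = z_latent[:, tj]
        c = config.edge_strength
        for _ in range(n_edges):
            gi = free_genes.pop(0)
            G[here, gi] += c * z[here]
            group_edges[group].append((taxa_ids[tj], gene_ids[gi], c))
            if config.edge_mode == "flip":
                G[~here, gi] += -c * z[~here]
                other = "B" if group == "A" else "A"
                group_edges[other].append((taxa_ids[tj], gene_ids[gi], -c))

    taxa_mx = OmicsMatrix(
        data=pd.DataFrame(counts.T, index=pd.Index(taxa_ids, name="taxon"), columns=samples),
        kind="taxon",
        unit="counts",
    )
    genes_mx = OmicsMatrix(
        data=pd.DataFrame(G.T, index=pd.Index(gene_ids, name="gene"), columns=samples),
        kind="gene",
        unit="log",
    )
    meta = SampleMetadata(meta_df)

    # --- synthetic cell-type enrichment scores ----------------------------
    cells = None
    variance_truth: dict = {}
    if config.n_celltypes:
        clr_vals = clr_transform(taxa_mx, pseudocount=0.5).values.to_numpy()
        scores = np.empty((n, config.n_celltypes))
        for k in range(config.n_celltypes):
            picked = rng.choice(config.n_taxa, size=config.celltype_taxa, replace=False)
            coefs = rng.uniform(0.5, 1.5, config.celltype_taxa)
            signal = clr_vals[:, picked] @ coefs
            noise_sd = math.sqrt(signal.var() * (1.0 - config.celltype_r2) / config.celltype_r2)
            scores[:, k] = signal + rng.normal(0.0, noise_sd, n)
            variance_truth[f"CT{k + 1:02d}"] = {
                "bacteria": config.celltype_r2,
                "taxa": [taxa_ids[j] for j in picked],
            }
        cells = OmicsMatrix(
            data=pd.DataFrame(
                scores.T,
                index=pd.Index([f"CT{k + 1:02d}" for k in range(config.n_celltypes)], name="celltype"),
                columns=samples,
            ),
            kind="celltype",
            unit="score",
        )

    truth = GroundTruth(
        module_members=module_members,
        interaction_truth=interaction_truth,
        group_edges={g: e for g, e in group_edges.items() if e},
        dysbiotic_samples=[samples[i] for i in np.where(dys_mask)[0]],
        variance_truth=variance_truth,
        de_genes=de_list,
    )
    truth.validate_ids(genes_mx, taxa_mx, meta)
    return Cohort(genes=genes_mx, taxa=taxa_mx, meta=meta, truth=truth, cells=cells)


def generate_null_cohort(config: SynthConfig) -> Cohort:
    """Cohort with no planted signal: covariate and patient effects retained,
    but no modules, interaction pairs or group-specific edges."""
    null_cfg = dataclasses.replace(
        config,
        n_modules=0,
        interaction_pairs=0,
        group_specific_edges=(0, 0),
        de_genes=0,
    )
    return generate_cohort(null_cfg)


def write_fixture(
    genes: OmicsMatrix,
    taxa: OmicsMatrix,
    meta: SampleMetadata,
    truth: GroundTruth,
    directory: str | Path,
    cells: Optional[OmicsMatrix] = None,
) -> dict[str, Path]:
    """Write a cohort as TSV matrices + metadata TSV + truth JSON.

    Round-trips losslessly through :mod:`mucolink.io` readers.
    """
    if taxa.n_features == 0 or taxa.n_samples == 0:
        raise ValueError("refusing to write an empty taxa matrix")
    if genes.n_features == 0 or genes.n_samples == 0:
        raise ValueError("refusing to write an empty gene matrix")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": directory / "genes.tsv",
        "taxa": directory / "taxa.tsv",
        "meta": directory / "metadata.tsv",
        "truth": directory / "truth.json",
    }
    genes.data.to_csv(paths["genes"], sep="\t")
    taxa.data.to_csv(paths["taxa"], sep="\t")
    meta.data.to_csv(paths["meta"], sep="\t")
    paths["truth"].write_text(truth.to_json())
    if cells is not None:
        paths["cells"] = directory / "celltypes.tsv"
        cells.data.to_csv(paths["cells"], sep="\t")
    return paths
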