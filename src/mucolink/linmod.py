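"""Random-intercept linear mixed models and the per-pair association scans.

Every regression in the package is a Gaussian linear mixed model

    y = X beta + Z u + e,   u ~ N(0, sigma2_u I),   e ~ N(0, sigma2_e I),

with one random intercept per patient (Z is the patient incidence matrix), so
repeated biopsies from the same patient are not treated as independent.

Estimation is REML, profiled down to a one-dimensional search over the
variance ratio gamma = sigma2_u / sigma2_e. With V_gamma = I + gamma Z Z',
the eigendecomposition Z Z' = U diag(s) U' (computed once per patient
grouping and reused across thousands of per-pair fits) turns every REML
evaluation into weighted least squares with weights 1 / (1 + gamma s_i).
The search is a golden-section minimization of the -2 REML criterion over
log(gamma) in [-12, 12], with the exact gamma = 0 (ordinary least squares)
boundary always evaluated as a candidate. Inference on fixed effects uses
Wald t statistics with df = n - rank(X).

The module also carries the shared scalar statistics: Benjamini-Hochberg
adjustment and the two Wilcoxon tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import qr as _qr

from .compositional import ClrMatrix, DysbiosisResult
from .containers import OmicsMatrix, SampleMetadata

logger = logging.getLogger("mucolink.linmod")

__all__ = [
    "AliasingError",
    "LmmFit",
    "PermutationSummary",
    "GroupRotation",
    "build_design",
    "fit_lmm",
    "residualize",
    "association_scan",
    "interaction_scan",
    "permutation_fpr",
    "differential_test",
    "bh_adjust",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
]

_LOG_GAMMA_LO = -12.0
_LOG_GAMMA_HI = 12.0
_GOLDEN_TOL = 1e-8
_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


class AliasingError(ValueError):
    """Raised when a design matrix is rank-deficient (aliased columns)."""


@dataclass
class LmmFit:
    """REML fit of a random-intercept linear mixed model."""

    beta: pd.Series
    se: pd.Series
    t: pd.Series
    p: pd.Series
    sigma2_e: float
    sigma2_u: float
    blup: pd.Series
    df_resid: int
    loglik_reml: float
    resid_conditional: pd.Series

    @property
    def gamma(self) -> float:
        return self.sigma2_u / self.sigma2_e if self.sigma2_e > 0 else 0.0


@dataclass
class PermutationSummary:
    """Permutation-null summary for the dysbiosis-interaction scan."""

    n_rounds: int
    n_tested: int
    sig_counts: list = field(default_factory=list)

    @property
    def fpr_estimate(self) -> float:
        if self.n_tested == 0:
            return 0.0
        return float(np.mean(self.sig_counts)) / self.n_tested


# ---------------------------------------------------------------------------
# design construction


def _check_rank(X: np.ndarray, names: Sequence[str]) -> int:
    """Column rank via pivoted QR; raises AliasingError naming aliased columns."""
    if X.shape[0] <= X.shape[1]:
        raise ValueError(
            f"need more observations ({X.shape[0]}) than design columns ({X.shape[1]})"
        )
    R, piv = _qr(X, mode="r", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        aliased = [names[j] for j in piv[rank:]]
        raise AliasingError(f"design is rank-deficient; aliased columns: {aliased}")
    return rank


def build_design(
    meta: SampleMetadata | pd.DataFrame,
    covariates: Sequence[str],
    add_intercept: bool = True,
) -> pd.DataFrame:
    """Fixed-effect design matrix from metadata columns.

    Numeric columns enter as-is. Categorical / string / boolean columns are
    treatment-coded with the first sorted level as the reference, so encoding
    is reproducible regardless of row order.
    """
    df = meta.data if isinstance(meta, SampleMetadata) else meta
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise KeyError(f"metadata is missing covariates: {missing}")
    cols: dict[str, np.ndarray] = {}
    if add_intercept:
        cols["Intercept"] = np.ones(len(df))
    for c in covariates:
        col = df[c]
        if col.isna().any():
            raise ValueError(
                f"covariate {c!r} has missing values; drop those samples first "
                "(imputation is out of scope)"
            )
        if np.issubdtype(col.dtype, np.number) and col.dtype != bool:
            cols[c] = col.to_numpy(dtype=float)
        else:
            levels = sorted(pd.unique(col.astype(str)))
            for lev in levels[1:]:
                cols[f"{c}[{lev}]"] = (col.astype(str) == lev).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=df.index)


# ---------------------------------------------------------------------------
# REML core


@dataclass
class GroupRotation:
    """Eigendecomposition of the patient-incidence structure Z Z'.

    Computed once per grouping vector; ``rotate`` maps any response or design
    column into the coordinate system where V_gamma is diagonal.
    """

    U: np.ndarray  # n x n orthogonal
    s: np.ndarray  # eigenvalues of Z Z' (group sizes spread across the spectrum)
    codes: np.ndarray
    group_labels: pd.Index
    index: pd.Index

    @classmethod
    def from_groups(cls, groups: pd.Series | Sequence) -> "GroupRotation":
        groups = pd.Series(np.asarray(groups)) if not isinstance(groups, pd.Series) else groups
        codes, labels = pd.factorize(groups)
        n = len(codes)
        Z = np.zeros((n, len(labels)))
        Z[np.arange(n), codes] = 1.0
        s, U = np.linalg.eigh(Z @ Z.T)
        s = np.clip(s, 0.0, None)
        return cls(U=U, s=s, codes=codes, group_labels=pd.Index(labels), index=groups.index)

    @property
    def all_singletons(self) -> bool:
        return bool(np.max(np.bincount(self.codes)) == 1)

    def rotate(self, M: np.ndarray) -> np.ndarray:
        return self.U.T @ M


def _wls_pieces(Xr: np.ndarray, yr: np.ndarray, w: np.ndarray):
    Xw = Xr * w[:, None]
    A = Xr.T @ Xw
    b = Xw.T @ yr
    beta = np.linalg.solve(A, b)
    resid = yr - Xr @ beta
    rss = float(np.dot(w * resid, resid))
    return A, beta, resid, rss


def _reml_crit(loggam: float, Xr: np.ndarray, yr: np.ndarray, s: np.ndarray, rank: int) -> float:
    gam = math.exp(loggam)
    w = 1.0 / (1.0 + gam * s)
    A, _, _, rss = _wls_pieces(Xr, yr, w)
    n = yr.shape[0]
    if rss <= 0:
        return -np.inf
    sign, ld = np.linalg.slogdet(A)
    return (n - rank) * math.log(rss / (n - rank)) + float(np.sum(np.log1p(gam * s))) + ld


def _ols_crit(Xr: np.ndarray, yr: np.ndarray, rank: int) -> float:
    w = np.ones_like(yr)
    A, _, _, rss = _wls_pieces(Xr, yr, w)
    n = yr.shape[0]
    if rss <= 0:
        return -np.inf
    sign, ld = np.linalg.slogdet(A)
    return (n - rank) * math.log(rss / (n - rank)) + ld


def _golden_min(f, a: float, b: float, tol: float) -> float:
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def _profile_gamma(Xr: np.ndarray, yr: np.ndarray, s: np.ndarray, rank: int) -> tuple[float, float]:
    """Return (gamma_hat, -2 REML criterion at gamma_hat); gamma=0 means OLS."""
    crit0 = _ols_crit(Xr, yr, rank)
    lg = _golden_min(lambda t: _reml_crit(t, Xr, yr, s, rank), _LOG_GAMMA_LO, _LOG_GAMMA_HI, _GOLDEN_TOL)
    crit_hat = _reml_crit(lg, Xr, yr, s, rank)
    if crit0 <= crit_hat + 1e-10:
        return 0.0, crit0
    return math.exp(lg), crit_hat


def _fit_core(Xr: np.ndarray, yr: np.ndarray, s: np.ndarray, rank: int, singleton: bool):
    """Numeric fit in rotated coordinates; returns a plain dict (hot path)."""
    n = yr.shape[0]
    if singleton:
        gam, crit = 0.0, _ols_crit(Xr, yr, rank)
    else:
        gam, crit = _profile_gamma(Xr, yr, s, rank)
    w = np.ones(n) if gam == 0.0 else 1.0 / (1.0 + gam * s)
    A, beta, resid_r, rss = _wls_pieces(Xr, yr, w)
    df = n - rank
    sigma2_e = rss / df
    cov = sigma2_e * np.linalg.inv(A)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    loglik = -0.5 * (crit + df * (1.0 + math.log(2.0 * math.pi)))
    return {
        "beta": beta,
        "se": se,
        "t": t,
        "p": p,
        "gamma": gam,
        "sigma2_e": sigma2_e,
        "sigma2_u": gam * sigma2_e,
        "df": df,
        "loglik": loglik,
    }


def fit_lmm(
    y: pd.Series | np.ndarray,
    X: pd.DataFrame | np.ndarray,
    groups: pd.Series | Sequence,
    rotation: Optional[GroupRotation] = None,
) -> LmmFit:
    """Fit the random-intercept LMM by REML.

    Parameters
    ----------
    y
        Response vector (length n).
    X
        Fixed-effect design, n x p, full column rank (an intercept column is
        the caller's responsibility; see :func:`build_design`).
    groups
        Patient ID per observation; defines the random intercept.
    rotation
        Optional precomputed :class:`GroupRotation` for this grouping (reused
        across many fits in the scan functions).

    Notes
    -----
    When every patient contributes a single observation the random intercept
    is unidentifiable; the fit then returns the boundary sigma2_u = 0 and
    coincides with ordinary least squares.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
        idx = X.index
    else:
        Xv = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xv.shape[1])]
        idx = pd.RangeIndex(Xv.shape[0])
    yv = np.asarray(y, dtype=float).ravel()
    if yv.shape[0] != Xv.shape[0]:
        raise ValueError("y and X have incompatible lengths")
    if not np.all(np.isfinite(Xv)) or not np.all(np.isfinite(yv)):
        raise ValueError("non-finite values in y or X; missing data must be dropped upstream")
    rank = _check_rank(Xv, names)
    if rotation is None:
        rotation = GroupRotation.from_groups(
            groups if isinstance(groups, pd.Series) else pd.Series(np.asarray(groups), index=idx)
        )
    Xr = rotation.rotate(Xv)
    yr = rotation.rotate(yv)
    res = _fit_core(Xr, yr, rotation.s, rank, rotation.all_singletons)

    # BLUP of the per-patient intercepts and conditional residuals
    gam = res["gamma"]
    marg = yv - Xv @ res["beta"]
    blup_vals = np.zeros(len(rotation.group_labels))
    if gam > 0:
        for g in range(len(rotation.group_labels)):
            mask = rotation.codes == g
            ng = int(mask.sum())
            blup_vals[g] = gam * marg[mask].sum() / (1.0 + gam * ng)
    blup = pd.Series(blup_vals, index=rotation.group_labels, name="blup")
    cond_resid = pd.Series(marg - blup_vals[rotation.codes], index=idx, name="resid")

    return LmmFit(
        beta=pd.Series(res["beta"], index=names),
        se=pd.Series(res["se"], index=names),
        t=pd.Series(res["t"], index=names),
        p=pd.Series(res["p"], index=names),
        sigma2_e=float(res["sigma2_e"]),
        sigma2_u=float(res["sigma2_u"]),
        blup=blup,
        df_resid=int(res["df"]),
        loglik_reml=float(res["loglik"]),
        resid_conditional=cond_resid,
    )


# ---------------------------------------------------------------------------
# feature-level operations


def _aligned(features: OmicsMatrix, meta: SampleMetadata):
    samples = [s for s in features.samples if s in meta.samples]
    dropped = features.n_samples - len(samples)
    if dropped:
        logger.info("dropping %d samples absent from metadata", dropped)
    if not samples:
        raise ValueError("no samples shared between features and metadata")
    return features.subset_samples(samples), meta.subset(samples)


def residualize(
    features: OmicsMatrix,
    meta: SampleMetadata,
    covariates: Sequence[str],
    groups: Optional[pd.Series] = None,
) -> OmicsMatrix:
    """Remove covariate and patient effects from every feature.

    Per feature the conditional residual ``y - X beta - blup(patient)`` is
    returned, i.e. the signal left after both the fixed covariates and the
    predicted per-patient intercept are subtracted. This is the input the
    sparse-CCA stage works on.
    """
    features, meta = _aligned(features, meta)
    if groups is None:
        groups = meta.patients
    X = build_design(meta, covariates)
    Xv = X.to_numpy(dtype=float)
    rank = _check_rank(Xv, list(X.columns))
    rot = GroupRotation.from_groups(groups)
    Xr = rot.rotate(Xv)
    Y = features.values  # features x samples
    if not np.all(np.isfinite(Y)):
        raise ValueError("feature matrix contains non-finite values")
    Yr = rot.rotate(Y.T)  # samples x features, rotated
    out = np.empty_like(Y)
    for i in range(features.n_features):
        res = _fit_core(Xr, Yr[:, i], rot.s, rank, rot.all_singletons)
        marg = Y[i] - Xv @ res["beta"]
        gam = res["gamma"]
        if gam > 0:
            for g in range(len(rot.group_labels)):
                mask = rot.codes == g
                ng = int(mask.sum())
                marg[mask] -= gam * marg[mask].sum() / (1.0 + gam * ng)
        out[i] = marg
    data = pd.DataFrame(out, index=features.features, columns=features.samples)
    return OmicsMatrix(data=data, kind=features.kind, unit="residual")


def _clr_frame(taxa_clr: ClrMatrix | OmicsMatrix) -> pd.DataFrame:
    """Samples x taxa frame from either a ClrMatrix or a features x samples OmicsMatrix."""
    if isinstance(taxa_clr, ClrMatrix):
        return taxa_clr.values
    return taxa_clr.data.T


def _scan_prep(
    genes: OmicsMatrix,
    taxa_frame: pd.DataFrame,
    meta: SampleMetadata,
    covariates: Sequence[str],
    groups: Optional[pd.Series],
):
    samples = [s for s in genes.samples if s in taxa_frame.index and s in meta.samples]
    if len(samples) < 10:
        raise ValueError("fewer than 10 shared samples across genes, taxa and metadata")
    genes = genes.subset_samples(samples)
    taxa_frame = taxa_frame.loc[samples]
    meta = meta.subset(samples)
    if groups is None:
        groups = meta.patients
    elif isinstance(groups, pd.Series):
        groups = groups.loc[samples]
    else:
        raise TypeError("groups must be a pandas Series indexed by sample ID (or None)")
    C = build_design(meta, covariates)
    _check_rank(C.to_numpy(dtype=float), list(C.columns))
    rot = GroupRotation.from_groups(groups)
    G = genes.values.T  # samples x genes
    T = taxa_frame.to_numpy(dtype=float)  # samples x taxa
    if not np.all(np.isfinite(G)) or not np.all(np.isfinite(T)):
        raise ValueError("non-finite values in gene or taxon matrix")
    return genes, taxa_frame, meta, C, rot, G, T


def _variable(v: np.ndarray) -> bool:
    return float(np.std(v)) > 1e-10


def association_scan(
    genes: OmicsMatrix,
    taxa_clr: ClrMatrix | OmicsMatrix,
    meta: SampleMetadata,
    covariates: Sequence[str],
    groups: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Per-pair gene ~ taxon LMM scan.

    For every (gene, taxon) pair, fits
    ``gene ~ intercept + taxon + covariates + (1 | patient)`` and reports the
    taxon slope with its Wald t test. BH adjustment is applied jointly across
    all pairs in the scan; the table is sorted by p.
    """
    taxa_frame = _clr_frame(taxa_clr)
    genes, taxa_frame, meta, C, rot, G, T = _scan_prep(genes, taxa_frame, meta, covariates, groups)
    Cv = C.to_numpy(dtype=float)
    p0 = Cv.shape[1]
    rank = p0 + 1
    Cr = rot.rotate(Cv)
    Gr = rot.rotate(G)
    Tr = rot.rotate(T)
    singleton = rot.all_singletons

    rows = []
    n_skipped = 0
    for tj, taxon in enumerate(taxa_frame.columns):
        if not _variable(T[:, tj]):
            n_skipped += G.shape[1]
            logger.info("skipping constant taxon %s", taxon)
            continue
        Xr = np.column_stack([Cr, Tr[:, tj]])
        for gi, gene in enumerate(genes.features):
            if not _variable(G[:, gi]):
                n_skipped += 1
                continue
            res = _fit_core(Xr, Gr[:, gi], rot.s, rank, singleton)
            rows.append(
                (gene, taxon, res["beta"][p0], res["se"][p0], res["t"][p0], res["p"][p0])
            )
    if n_skipped:
        logger.info("association_scan skipped %d constant pairs", n_skipped)
    out = pd.DataFrame(rows, columns=["gene_id", "taxon_id", "beta", "se", "t", "p"])
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    else:
        out["p_adj"] = []
    return out


def _dysbiosis_indicator(dysbiosis, samples: pd.Index) -> np.ndarray:
    if isinstance(dysbiosis, DysbiosisResult):
        flags = dysbiosis.is_dysbiotic
    else:
        flags = pd.Series(dysbiosis)
        if flags.dtype == object:
            flags = flags == "dysbiotic"
    missing = [s for s in samples if s not in flags.index]
    if missing:
        raise ValueError(f"dysbiosis status missing for samples: {missing[:5]}")
    return flags.loc[samples].to_numpy(dtype=float)


def interaction_scan(
    genes: OmicsMatrix,
    taxa_clr: ClrMatrix | OmicsMatrix,
    dysbiosis: DysbiosisResult | pd.Series,
    meta: SampleMetadata,
    covariates: Sequence[str],
    groups: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Dysbiosis-conditional interaction scan.

    Per pair, fits ``gene ~ taxon + dysbiosis + taxon:dysbiosis + covariates +
    (1 | patient)`` and tests the interaction coefficient. The reported
    eubiotic slope is the taxon main effect; the dysbiotic slope is main
    effect + interaction. BH is applied to the interaction p-values across all
    pairs. A pair whose smaller dysbiosis stratum has fewer than 10 samples is
    flagged ``low_power`` but still fitted.
    """
    taxa_frame = _clr_frame(taxa_clr)
    genes, taxa_frame, meta, C, rot, G, T = _scan_prep(genes, taxa_frame, meta, covariates, groups)
    d = _dysbiosis_indicator(dysbiosis, genes.samples)
    if not _variable(d):
        raise AliasingError("dysbiosis status is constant; the interaction is inestimable")
    return _interaction_core(genes, taxa_frame, C, rot, G, T, d)


def _interaction_core(genes, taxa_frame, C, rot, G, T, d) -> pd.DataFrame:
    Cv = C.to_numpy(dtype=float)
    p0 = Cv.shape[1]
    rank = p0 + 3
    Cr = rot.rotate(Cv)
    Gr = rot.rotate(G)
    Tr = rot.rotate(T)
    dr = rot.rotate(d)
    TDr = rot.rotate(T * d[:, None])
    singleton = rot.all_singletons
    n_small = int(min(d.sum(), (1 - d).sum()))
    low_power = n_small < 10

    i_main, i_dys, i_int = p0, p0 + 1, p0 + 2
    rows = []
    for tj, taxon in enumerate(taxa_frame.columns):
        if not _variable(T[:, tj]):
            logger.info("skipping constant taxon %s", taxon)
            continue
        if not _variable(T[:, tj] * d):
            logger.info("skipping taxon %s: interaction column constant", taxon)
            continue
        Xr = np.column_stack([Cr, Tr[:, tj], dr, TDr[:, tj]])
        for gi, gene in enumerate(genes.features):
            if not _variable(G[:, gi]):
                continue
            res = _fit_core(Xr, Gr[:, gi], rot.s, rank, singleton)
            b = res["beta"]
            rows.append(
                (
                    gene,
                    taxon,
                    b[i_main],
                    b[i_dys],
                    b[i_int],
                    res["se"][i_int],
                    res["p"][i_int],
                    b[i_main],
                    b[i_main] + b[i_int],
                    low_power,
                )
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "taxon_id",
            "beta_main",
            "beta_dysbiosis",
            "beta_interaction",
            "se_interaction",
            "p_interaction",
            "slope_eubiotic",
            "slope_dysbiotic",
            "low_power",
        ],
    )
    if len(out):
        out["p_adj"] = bh_adjust(out["p_interaction"].to_numpy())
        out = out.sort_values("p_interaction", kind="mergesort").reset_index(drop=True)
    else:
        out["p_adj"] = []
    return out


def permutation_fpr(
    genes: OmicsMatrix,
    taxa_clr: ClrMatrix | OmicsMatrix,
    dysbiosis: DysbiosisResult | pd.Series,
    meta: SampleMetadata,
    covariates: Sequence[str],
    groups: Optional[pd.Series] = None,
    n_rounds: int = 100,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> PermutationSummary:
    """Empirical false-positive rate of the interaction scan under shuffled dysbiosis.

    Each round permutes the dysbiosis labels across samples (the dysbiotic
    count is preserved by construction), reruns the interaction scan, and
    records how many pairs remain BH-significant at ``alpha``. The mean count
    divided by the number of tested pairs estimates the scan's false-positive
    rate.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    taxa_frame = _clr_frame(taxa_clr)
    genes, taxa_frame, meta, C, rot, G, T = _scan_prep(genes, taxa_frame, meta, covariates, groups)
    d = _dysbiosis_indicator(dysbiosis, genes.samples)
    if not _variable(d):
        raise AliasingError("dysbiosis status is constant; the interaction is inestimable")
    rng = np.random.default_rng(seed)
    n_dys = int(d.sum())
    sig_counts = []
    n_tested = None
    for _ in range(n_rounds):
        d_perm = rng.permutation(d)
        assert int(d_perm.sum()) == n_dys  # shuffling must preserve the dysbiotic count
        tab = _interaction_core(genes, taxa_frame, C, rot, G, T, d_perm)
        n_tested = len(tab)
        sig_counts.append(int((tab["p_adj"] < alpha).sum()))
    return PermutationSummary(n_rounds=n_rounds, n_tested=int(n_tested or 0), sig_counts=sig_counts)


def differential_test(
    features: OmicsMatrix,
    meta: SampleMetadata,
    contrast: str,
    covariates: Sequence[str],
    groups: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Per-feature differential test on a metadata contrast.

    Fits ``feature ~ contrast + covariates + (1 | patient)`` per feature and
    reports the Wald t test on the contrast coefficient, BH-adjusted across
    features. The contrast may be binary or continuous; a categorical contrast
    with >2 levels is rejected (test its dummies separately).
    """
    features, meta = _aligned(features, meta)
    if contrast in covariates:
        raise ValueError("contrast must not also appear in the covariate list")
    design = build_design(meta, list(covariates) + [contrast])
    contrast_cols = [c for c in design.columns if c == contrast or c.startswith(f"{contrast}[")]
    if len(contrast_cols) != 1:
        raise ValueError(
            f"contrast {contrast!r} must be binary or continuous (got columns {contrast_cols})"
        )
    ci = design.columns.get_loc(contrast_cols[0])
    Xv = design.to_numpy(dtype=float)
    try:
        rank = _check_rank(Xv, list(design.columns))
    except AliasingError as err:
        raise AliasingError(f"contrast {contrast!r} is aliased with the covariates: {err}") from err
    if groups is None:
        groups = meta.patients
    rot = GroupRotation.from_groups(groups)
    Xr = rot.rotate(Xv)
    Y = features.values
    Yr = rot.rotate(Y.T)
    rows = []
    for i, feat in enumerate(features.features):
        if not _variable(Y[i]):
            logger.info("skipping constant feature %s", feat)
            continue
        res = _fit_core(Xr, Yr[:, i], rot.s, rank, rot.all_singletons)
        rows.append((feat, contrast, res["beta"][ci], res["se"][ci], res["t"][ci], res["p"][ci]))
    out = pd.DataFrame(rows, columns=["gene_id", "taxon_id", "beta", "se", "t", "p"])
    out = out.rename(columns={"taxon_id": "contrast"})
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    else:
        out["p_adj"] = []
    return out


def rank_inverse_normal(features: OmicsMatrix, c: float = 3.0 / 8.0) -> OmicsMatrix:
    """Blom rank-inverse-normal transform of each feature across samples.

    An alternative predictor scale for the association scans when CLR values
    are heavy-tailed: ranks are mapped through the normal quantile function
    ``Phi^-1((r - c) / (n - 2c + 1))``.
    """
    vals = features.values
    n = vals.shape[1]
    out = np.empty_like(vals)
    for i in range(vals.shape[0]):
        r = sps.rankdata(vals[i], method="average")
        out[i] = sps.norm.ppf((r - c) / (n - 2 * c + 1))
    return OmicsMatrix(
        data=pd.DataFrame(out, index=features.features, columns=features.samples),
        kind=features.kind,
        unit=features.unit,
    )


# ---------------------------------------------------------------------------
# scalar statistics


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Standard definition: sort ascending, multiply p_(i) by m/i, enforce
    monotonicity with a cumulative minimum from the largest p down, clip at 1,
    and map back to the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


_EXACT_N = 25


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact null distribution when both samples have <= 25 observations and no
    ties straddle the groups; otherwise the tie-corrected normal
    approximation. Returns (U statistic for the first sample, p-value).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 observations per group")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(a.size, b.size) <= _EXACT_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(d: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are discarded; at least 3 nonzero differences are
    required. Exact for <= 25 untied absolute differences, otherwise the
    normal approximation.
    """
    d = np.asarray(d, dtype=float)
    nz = d[d != 0]
    if nz.size == 0:
        raise ValueError("all paired differences are zero")
    if nz.size < 3:
        raise ValueError("need at least 3 nonzero paired differences")
    has_ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= _EXACT_N and not has_ties) else "approx"
    res = sps.wilcoxon(nz, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
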