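"""Compositional transforms, diversity, Aitchison geometry, PERMANOVA and the
dysbiosis score.

Taxon count tables are compositional: only relative information is meaningful
and the sampling depth is an artifact of sequencing. All distance-based
analyses here therefore act on centered log-ratio (CLR) coordinates, where
Euclidean distance between samples is the Aitchison distance. The per-sample
dysbiosis score is the median Aitchison distance to a set of reference
(non-IBD control) samples; samples strictly above a quantile of the score
distribution (default the 90th percentile) are called dysbiotic, the rest
eubiotic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import OmicsMatrix

logger = logging.getLogger("mucolink.compositional")

__all__ = [
    "ClrMatrix",
    "DysbiosisResult",
    "PermanovaResult",
    "clr_transform",
    "shannon_index",
    "aitchison_distance",
    "dysbiosis_score",
    "permanova",
]


@dataclass
class ClrMatrix:
    """Samples x features matrix on the CLR scale.

    Every row sums to zero (up to floating-point error) by construction.
    """

    values: pd.DataFrame
    pseudocount: float

    def __post_init__(self) -> None:
        rowsums = self.values.sum(axis=1).to_numpy()
        if self.values.shape[1] > 0 and np.max(np.abs(rowsums)) > 1e-6:
            raise ValueError("CLR rows must sum to zero")

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def features(self) -> pd.Index:
        return self.values.columns


@dataclass
class DysbiosisResult:
    """Per-sample dysbiosis score and eubiotic/dysbiotic classification."""

    score: pd.Series
    threshold: float
    status: pd.Series  # "eubiotic" | "dysbiotic"
    reference_ids: list = field(default_factory=list)
    quantile: float = 0.9

    @property
    def is_dysbiotic(self) -> pd.Series:
        return self.status == "dysbiotic"


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("PERMANOVA p-value must lie in (0, 1]")
        if self.p_value < 1.0 / (self.n_permutations + 1) - 1e-12:
            raise ValueError("p-value below the permutation resolution 1/(B+1)")


def clr_transform(counts: OmicsMatrix, pseudocount: float = 0.5) -> ClrMatrix:
    """Centered log-ratio transform of a taxon count matrix.

    For sample i and feature j, ``clr_ij = log(x_ij + pc) - mean_j log(x_ij + pc)``.
    A uniform additive pseudocount (default 0.5 counts) handles zeros;
    ``pseudocount=0`` is allowed only for strictly positive matrices.

    Parameters
    ----------
    counts
        Features x samples nonnegative matrix.
    pseudocount
        Additive constant applied to every entry before taking logs.
    """
    X = counts.values.T  # samples x features
    if X.shape[1] == 0:
        raise ValueError("cannot CLR-transform a matrix with zero features")
    if np.any(X < 0):
        raise ValueError("counts must be nonnegative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    zero_rows = np.where(X.sum(axis=1) == 0)[0]
    if zero_rows.size:
        ids = counts.samples[zero_rows].tolist()
        raise ValueError(f"all-zero samples cannot be CLR-transformed: {ids[:5]}")
    if pseudocount == 0 and np.any(X == 0):
        raise ValueError("pseudocount=0 requires strictly positive counts")
    L = np.log(X + pseudocount)
    L -= L.mean(axis=1, keepdims=True)
    vals = pd.DataFrame(L, index=counts.samples, columns=counts.features)
    return ClrMatrix(values=vals, pseudocount=pseudocount)


def shannon_index(counts: OmicsMatrix) -> pd.Series:
    """Shannon alpha-diversity H = -sum p ln p over relative abundances.

    The convention 0*ln(0) = 0 applies, so structural zeros contribute nothing.
    """
    X = counts.values.T
    if np.any(X < 0):
        raise ValueError("counts must be nonnegative")
    totals = X.sum(axis=1)
    zero_rows = np.where(totals == 0)[0]
    if zero_rows.size:
        ids = counts.samples[zero_rows].tolist()
        raise ValueError(f"all-zero samples have undefined diversity: {ids[:5]}")
    P = X / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P), 0.0)
    return pd.Series(-terms.sum(axis=1), index=counts.samples, name="shannon")


def aitchison_distance(clr: ClrMatrix) -> pd.DataFrame:
    """Pairwise Aitchison distances: Euclidean distance between CLR rows."""
    D = squareform(pdist(clr.values.to_numpy(), metric="euclidean"))
    return pd.DataFrame(D, index=clr.samples, columns=clr.samples)


def dysbiosis_score(
    clr: ClrMatrix,
    control_ids: Sequence[str],
    quantile: float = 0.9,
) -> DysbiosisResult:
    """Score each sample by its median Aitchison distance to reference controls.

    Control samples are scored leave-self-out (the median over the *other*
    controls) so their own zero self-distance cannot deflate the score. The
    classification threshold is the empirical ``quantile`` (linear
    interpolation) of the score vector over all scored samples; a sample is
    dysbiotic iff its score is strictly greater than the threshold.
    """
    control_ids = list(control_ids)
    if not (0.0 < quantile < 1.0):
        raise ValueError("quantile must lie in (0, 1)")
    missing = [c for c in control_ids if c not in clr.samples]
    if missing:
        raise KeyError(f"control samples absent from CLR matrix: {missing[:5]}")
    if len(control_ids) < 2:
        raise ValueError("need at least 2 reference control samples")

    D = aitchison_distance(clr)
    ref = D.loc[:, control_ids]
    scores = {}
    for s in clr.samples:
        d = ref.loc[s]
        if s in control_ids:
            d = d.drop(labels=[s])
        scores[s] = float(np.median(d.to_numpy()))
    score = pd.Series(scores, name="dysbiosis_score").loc[clr.samples]
    threshold = float(np.quantile(score.to_numpy(), quantile))
    status = pd.Series(
        np.where(score.to_numpy() > threshold, "dysbiotic", "eubiotic"),
        index=score.index,
        name="dysbiosis_status",
    )
    return DysbiosisResult(
        score=score,
        threshold=threshold,
        status=status,
        reference_ids=control_ids,
        quantile=quantile,
    )


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_levels: int) -> tuple[float, float]:
    """Total and within-group sums of squared distances (Anderson)."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_levels):
        idx = np.where(codes == g)[0]
        if idx.size < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    return ss_total, ss_within


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_levels: int) -> float:
    n = d2.shape[0]
    ss_total, ss_within = _permanova_ss(d2, codes, n_levels)
    ss_among = ss_total - ss_within
    df_among = n_levels - 1
    df_within = n - n_levels
    if df_within <= 0:
        raise ValueError("PERMANOVA needs n > number of groups")
    if ss_within <= 0:
        return np.inf if ss_among > 0 else 0.0
    return (ss_among / df_among) / (ss_within / df_within)


def permanova(
    dist: pd.DataFrame,
    labels: pd.Series | Sequence,
    n_permutations: int = 999,
    seed: Optional[int] = None,
    strata: Optional[pd.Series | Sequence] = None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Pseudo-F follows Anderson's among/within decomposition of squared
    distances; the p-value is ``(1 + #{F_perm >= F_obs}) / (B + 1)``. Labels
    are permuted freely by default; passing ``strata`` (e.g. patient IDs)
    restricts shuffling to within-stratum exchanges, respecting repeated
    measures.
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dist must be a square distance matrix")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    labels = pd.Series(np.asarray(labels), copy=False)
    if len(labels) != D.shape[0]:
        raise ValueError("labels length must match distance matrix size")
    codes, levels = pd.factorize(labels)
    if len(levels) < 2:
        raise ValueError("labels must have at least 2 levels")
    counts = np.bincount(codes)
    if counts.min() < 2:
        small = [str(levels[i]) for i in np.where(counts < 2)[0]]
        raise ValueError(f"each group needs >= 2 members; too small: {small}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")

    d2 = D**2
    f_obs = _pseudo_f(d2, codes, len(levels))
    rng = np.random.default_rng(seed)

    if strata is not None:
        strata = pd.Series(np.asarray(strata), copy=False)
        strata_idx = [np.where(strata.to_numpy() == s)[0] for s in strata.unique()]

    n_extreme = 0
    perm = codes.copy()
    for _ in range(n_permutations):
        if strata is None:
            perm = rng.permutation(codes)
        else:
            perm = codes.copy()
            for idx in strata_idx:
                perm[idx] = perm[rng.permutation(idx)]
        if _pseudo_f(d2, perm, len(levels)) >= f_obs - 1e-12:
            n_extreme += 1
    p = (1 + n_extreme) / (n_permutations + 1)
    return PermanovaResult(pseudo_f=float(f_obs), p_value=float(p), n_permutations=n_permutations)
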