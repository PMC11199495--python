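"""Diversity statistics: rarefaction, alpha metrics, Bray-Curtis,
principal coordinate analysis and permutational MANOVA.

Alpha diversity (observed richness and inverse Simpson) is computed on
counts rarefied without replacement to a common depth; samples below
the depth are excluded, mirroring survey practice.  Community
dissimilarity is abundance-based Bray-Curtis on taxon-aggregated
relative abundances; its structure is summarised by classical metric
scaling (PCoA) and the variance explained by single metadata factors
is quantified with a distance-based permutational analysis of variance
(pseudo-F, R-squared, permutation p-value).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import InvalidInputError


@dataclass(frozen=True)
class DiversityParams:
    """Rarefaction depth and permutation settings."""

    rarefaction_depth: int = 10_000
    n_permutations: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rarefaction_depth < 1 or self.n_permutations < 1:
            raise InvalidInputError(
                "depth and permutation count must be >= 1")


def rarefy(table: pd.DataFrame, depth: int = 10_000,
           seed: int | np.random.Generator = 0,
           ) -> tuple[pd.DataFrame, list[str]]:
    """Subsample each sample's reads without replacement to *depth*.

    Samples whose total falls short of the depth are excluded and
    listed.  Rarefied totals equal the depth exactly (multivariate
    hypergeometric draw).  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed) \
        if isinstance(seed, (int, np.integer)) else seed
    kept = []
    excluded = []
    rows = []
    for sample in table.index:
        counts = table.loc[sample].to_numpy()
        if counts.sum() < depth:
            excluded.append(sample)
            continue
        rows.append(rng.multivariate_hypergeometric(counts, depth))
        kept.append(sample)
    out = pd.DataFrame(rows, index=kept, columns=table.columns,
                       dtype=np.int64)
    return out, excluded


def alpha_diversity(table: pd.DataFrame) -> pd.DataFrame:
    """Observed richness and inverse Simpson (1 / sum p_i^2) per sample."""
    totals = table.sum(axis=1)
    if (totals <= 0).any():
        raise InvalidInputError(
            f"all-zero samples: {list(totals.index[totals <= 0])}")
    p = table.div(totals, axis=0)
    richness = (table > 0).sum(axis=1)
    inv_simpson = 1.0 / (p ** 2).sum(axis=1)
    return pd.DataFrame({"observed_richness": richness,
                         "inverse_simpson": inv_simpson})


def bray_curtis(rel: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix between samples.

    d(a, b) = 1 - 2 * sum min(a_i, b_i) / sum (a_i + b_i); symmetric
    with zero diagonal, bounded in [0, 1] for non-negative input.
    """
    if rel.shape[0] < 2:
        raise InvalidInputError("need at least 2 samples")
    d = squareform(pdist(rel.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(d, index=rel.index, columns=rel.index)


@dataclass(frozen=True)
class PCoAResult:
    """Coordinates, eigenvalues and per-axis explained variance."""

    coordinates: pd.DataFrame    # samples x retained axes
    eigenvalues: np.ndarray      # all eigenvalues, descending
    explained: np.ndarray        # fraction of positive-eigenvalue sum


def pcoa(dm: pd.DataFrame) -> PCoAResult:
    """Classical metric scaling of a dissimilarity matrix.

    The squared-distance matrix is double-centred and
    eigendecomposed; axes are ordered by eigenvalue, explained
    variance is relative to the sum of positive eigenvalues, and
    negative eigenvalues are reported, not corrected.  Axis signs are
    fixed so the largest-magnitude loading on each axis is positive.
    """
    d = dm.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise InvalidInputError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    tol = max(1e-12, 1e-10 * abs(eigval[0])) if n else 0.0
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    for a in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, a])))
        if coords[i, a] < 0:
            coords[:, a] = -coords[:, a]
    pos_sum = eigval[pos].sum()
    explained = eigval[pos] / pos_sum if pos_sum > 0 else eigval[pos]
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return PCoAResult(pd.DataFrame(coords, index=dm.index, columns=cols),
                      eigval, explained)


@dataclass(frozen=True)
class PermanovaResult:
    """Distance-based one-factor variance partition."""

    factor: str
    r2: float
    pseudo_f: float
    p_value: float
    n_permutations: int
    method: str  # "permutation" or "exact"


def _ss_partition(d2: np.ndarray, codes: np.ndarray,
                  n_groups: int) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and group codes."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        z = codes == g
        ng = int(z.sum())
        ss_within += d2[np.ix_(z, z)].sum() / (2.0 * ng)
    return ss_total, ss_within


def permanova(dm: pd.DataFrame, labels: pd.Series | np.ndarray,
              n_permutations: int = 999,
              seed: int | np.random.Generator = 0,
              method: str = "permutation",
              factor: str = "") -> PermanovaResult:
    """One-factor PERMANOVA on a dissimilarity matrix.

    The total sum of squared distances partitions into within- and
    among-group components; pseudo-F = (SS_A / (a-1)) / (SS_W / (n-a))
    and R-squared = SS_A / SS_T.  ``method="permutation"`` estimates
    p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations) under free
    label permutation; ``method="exact"`` enumerates every distinct
    label arrangement (small n only) and reports the exact tail
    fraction #{F >= F_obs} / #arrangements.
    """
    labels = pd.Series(labels, index=dm.index) \
        if not isinstance(labels, pd.Series) else labels.loc[dm.index]
    cats, codes = np.unique(labels.to_numpy(), return_inverse=True)
    n = len(codes)
    n_groups = len(cats)
    if n_groups < 2:
        raise InvalidInputError("factor is constant")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise InvalidInputError(
            f"groups with fewer than 2 samples: "
            f"{[str(cats[i]) for i in np.flatnonzero(sizes < 2)]}")
    d2 = dm.to_numpy(dtype=float) ** 2

    def f_stat(c: np.ndarray) -> tuple[float, float]:
        ss_t, ss_w = _ss_partition(d2, c, n_groups)
        ss_a = ss_t - ss_w
        f = (ss_a / (n_groups - 1)) / (ss_w / (n - n_groups))
        return f, ss_a / ss_t

    f_obs, r2 = f_stat(codes)

    if method == "exact":
        seen = set()
        tail = 0
        total = 0
        for perm in itertools.permutations(codes):
            if perm in seen:
                continue
            seen.add(perm)
            total += 1
            f_p, _ = f_stat(np.array(perm))
            if f_p >= f_obs - 1e-12:
                tail += 1
        return PermanovaResult(factor, r2, f_obs, tail / total,
                               total, "exact")

    if method != "permutation":
        raise InvalidInputError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed) \
        if isinstance(seed, (int, np.integer)) else seed
    # Vectorised permutation scan: SS_within per permutation via the
    # quadratic form z' D2 z accumulated over groups.
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    perm_codes = codes[perms]                   # (n_perm, n)
    ss_w = np.zeros(n_permutations)
    for g in range(n_groups):
        z = (perm_codes == g).astype(float)
        ss_w += np.einsum("pi,ij,pj->p", z, d2, z) / (2.0 * sizes[g])
    ss_t = d2.sum() / (2.0 * n)
    f_perm = ((ss_t - ss_w) / (n_groups - 1)) / (ss_w / (n - n_groups))
    p = (1 + int((f_perm >= f_obs - 1e-12).sum())) / (1 + n_permutations)
    return PermanovaResult(factor, r2, f_obs, p, n_permutations,
                           "permutation")


def permanova_by_factor(dm: pd.DataFrame, metadata: pd.DataFrame,
                        factors: list[str],
                        params: DiversityParams | None = None,
                        ) -> pd.DataFrame:
    """Marginal PERMANOVA of each factor in isolation."""
    params = params or DiversityParams()
    rows = []
    for i, factor in enumerate(factors):
        res = permanova(dm, metadata[factor],
                        n_permutations=params.n_permutations,
                        seed=params.seed + i, factor=factor)
        rows.append({"factor": factor, "r2": res.r2,
                     "pseudo_f": res.pseudo_f, "p_value": res.p_value})
    return pd.DataFrame(rows)
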