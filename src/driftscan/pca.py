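"""Genomic PCA, per-population convex-hull polygon areas, and the exact
Wilcoxon signed-rank test.

Genomic variance among individuals is summarized by a PCA of centered,
unit-variance-scaled ALT dosages (missing calls mean-imputed per SNP).  For
each population and each of the C(6,2)=15 pairs of the first six components,
the area of the convex polygon linking the outermost individuals is the
population's genomic-variance proxy in that plane.  Areas of a target
generation are compared with a baseline generation by an exact Wilcoxon
signed-rank test whose null distribution is built by dynamic programming
over rank subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .errors import ValidationError
from .variant_io import MISSING, GenotypeMatrix

__all__ = [
    "PCAEmbedding",
    "WilcoxonResult",
    "genomic_pca",
    "pc_pairs",
    "hull_area",
    "population_areas",
    "signed_rank_null",
    "wilcoxon_signed_rank_exact",
    "compare_variance",
]

logger = logging.getLogger(__name__)


@dataclass
class PCAEmbedding:
    """Sample scores and eigenvalues of a genomic PCA."""

    scores: pd.DataFrame  # samples x PCs, indexed by sample_id
    eigenvalues: np.ndarray
    explained_frac: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass(frozen=True)
class WilcoxonResult:
    """Exact signed-rank test outcome.

    ``v_statistic`` is the sum of ranks of positive differences; the
    two-sided p-value is 2*min(P(V <= v), P(V >= v)) under the exact null,
    capped at 1.
    """

    v_statistic: float
    n_pairs: int
    p_two_sided: float
    exact: bool = True


def genomic_pca(gm: GenotypeMatrix, n_components: int = 15) -> PCAEmbedding:
    """PCA on scaled and centered genotype dosages.

    Missing dosages are imputed with the SNP mean before centering; each SNP
    column is scaled to unit variance.  Columns with zero variance after
    imputation are dropped (logged).  Component signs are fixed by making
    the largest-magnitude loading of each component positive.
    """
    if gm.n_samples < 2:
        raise ValidationError("PCA needs at least 2 samples")
    X = gm.dosage.astype(float)
    X[gm.dosage == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])

    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("genomic_pca: dropped %d zero-variance SNP columns", n_dropped)
    X = X[:, keep] / sd[keep]
    if X.shape[1] < n_components:
        raise ValidationError(
            f"need >= {n_components} polymorphic SNPs, have {X.shape[1]}"
        )

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    n = X.shape[0]
    eig_all = (s**2) / (n - 1)
    total_var = eig_all.sum()

    k = min(n_components, len(s))
    scores = U[:, :k] * s[:k]
    # deterministic sign: largest-|loading| positive
    for j in range(k):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            scores[:, j] *= -1
    cols = [f"PC{j + 1}" for j in range(k)]
    return PCAEmbedding(
        scores=pd.DataFrame(scores, index=pd.Index(gm.sample_ids, name="sample_id"), columns=cols),
        eigenvalues=eig_all[:k],
        explained_frac=eig_all[:k] / total_var,
    )


def pc_pairs(k: int = 6) -> list[tuple[int, int]]:
    """All unordered pairs (i, j), 1 <= i < j <= k, of the first k components."""
    if k < 2:
        raise ValidationError("k must be >= 2")
    return list(combinations(range(1, k + 1), 2))


def hull_area(points) -> float:
    """Convex-hull area of a set of 2-D points (shoelace on hull vertices).

    Degenerate inputs (< 3 points, collinear points) have area 0.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValidationError("at least one point is required")
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be an (n, 2) array")
    if len(pts) < 3:
        return 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return 0.0  # collinear or otherwise degenerate
    return float(hull.volume)  # in 2-D, .volume is the enclosed area


def population_areas(
    emb: PCAEmbedding, pop_map: pd.DataFrame, k: int = 6
) -> pd.DataFrame:
    """Convex-hull area per population for each pair of the first k PCs.

    Returns a DataFrame (population, pc_i, pc_j, area) with C(k,2) rows per
    population.  Populations with fewer than 3 samples get zero areas (with
    a warning).
    """
    pairs = pc_pairs(k)
    if emb.n_components < k:
        raise ValidationError(f"embedding has {emb.n_components} < {k} components")
    rows = []
    for pop, grp in pop_map.groupby("population", sort=False):
        ids = [s for s in grp["sample_id"] if s in emb.scores.index]
        sub = emb.scores.loc[ids]
        if len(sub) < 3:
            logger.warning("population %s has < 3 samples; areas set to 0", pop)
        for i, j in pairs:
            pts = sub[[f"PC{i}", f"PC{j}"]].to_numpy()
            area = hull_area(pts) if len(pts) >= 3 else 0.0
            rows.append({"population": pop, "pc_i": i, "pc_j": j, "area": area})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Exact Wilcoxon signed-rank


def signed_rank_null(n: int) -> np.ndarray:
    """Counts of rank subsets by rank-sum for n untied non-zero differences.

    Entry v of the returned array is the number of subsets of {1..n} with
    sum v; entries sum to 2**n.  Built by the classic dynamic programme
    (polynomial product of (1 + x^k))."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    max_sum = n * (n + 1) // 2
    counts = np.zeros(max_sum + 1, dtype=float)
    counts[0] = 1.0
    for k in range(1, n + 1):
        counts[k:] += counts[:-k].copy()
    return counts


def wilcoxon_signed_rank_exact(diffs) -> WilcoxonResult:
    """Exact two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; ranks are assigned to |differences|.  With
    no ties the exact null is used directly.  With ties, midranks are used;
    the distribution of V is then obtained by exact enumeration when
    n <= 12 and by a normal approximation with tie correction otherwise
    (``exact=False`` on the result).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValidationError("all differences are zero: test undefined")
    absd = np.abs(d)
    order = np.argsort(absd, kind="mergesort")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    # midranks over tied groups
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    v = float(ranks[d > 0].sum())
    has_ties = len(np.unique(sorted_abs)) < n

    if not has_ties:
        counts = signed_rank_null(n)
        total = counts.sum()
        vi = int(round(v))
        p_le = counts[: vi + 1].sum() / total
        p_ge = counts[vi:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(v, n, p, exact=True)

    if n <= 12:
        # enumerate all 2**n sign assignments with midranks
        sums = np.zeros(1)
        for r in ranks:
            sums = np.concatenate([sums, sums + r])
        p_le = (sums <= v + 1e-12).mean()
        p_ge = (sums >= v - 1e-12).mean()
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(v, n, p, exact=True)

    mean = ranks.sum() / 2.0
    var = np.square(ranks).sum() / 4.0
    from scipy.stats import norm

    z = (v - mean) / np.sqrt(var)
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    logger.warning("ties with n > 12: normal approximation used")
    return WilcoxonResult(v, n, p, exact=False)


def compare_variance(
    areas: pd.DataFrame,
    baseline_pops: list[str],
    target_pops: list[str],
    k: int = 6,
) -> WilcoxonResult:
    """Signed-rank comparison of polygon areas between two generations.

    ``baseline_pops`` and ``target_pops`` are paired positionally (e.g.
    baseline ``["A1", "B1"]`` against target ``["B9A", "B9B"]`` pairs
    replicate A with A and B with B).  For every pairing and every PC pair
    the difference target_area - baseline_area enters the test, giving
    2 x C(k,2) = 30 paired differences for two replicates.
    """
    if len(baseline_pops) != len(target_pops):
        raise ValidationError("baseline and target population lists must pair up")
    pairs = pc_pairs(k)
    diffs = []
    for base, targ in zip(baseline_pops, target_pops):
        a_base = _area_lookup(areas, base)
        a_targ = _area_lookup(areas, targ)
        for i, j in pairs:
            if (i, j) not in a_base or (i, j) not in a_targ:
                raise ValidationError(
                    f"PC pair ({i},{j}) missing for {base!r} or {targ!r}"
                )
            diffs.append(a_targ[(i, j)] - a_base[(i, j)])
    return wilcoxon_signed_rank_exact(np.asarray(diffs))


def _area_lookup(areas: pd.DataFrame, pop: str) -> dict:
    sub = areas[areas["population"] == pop]
    if sub.empty:
        raise ValidationError(f"no areas for population {pop!r}")
    return {(int(r.pc_i), int(r.pc_j)): float(r.area) for r in sub.itertuples()}
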