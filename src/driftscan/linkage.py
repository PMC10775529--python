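"""Linkage disequilibrium and haplotype-block structure.

LD between unphased diploid loci is measured as the squared Pearson
correlation of ALT-dosage vectors (the plink/vcftools ``--geno-r2``
statistic), with pairwise-complete handling of missing calls.  Two-locus
haplotype frequencies are estimated by EM over the double-heterozygote phase
ambiguity; D' confidence intervals follow the Gabriel-style normalized
likelihood on a |D'| grid, and haplotype blocks are spans whose SNP pairs
show predominantly "strong LD" (CI lower bound >= 0.70 and upper bound >=
0.98), up to a maximum span of 200 kb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .variant_io import MISSING, GenotypeMatrix

__all__ = [
    "LDPair",
    "HaplotypeBlock",
    "dosage_r2",
    "pairwise_r2",
    "ld_decay",
    "em_haplotype_freqs",
    "dprime_ci",
    "gabriel_blocks",
    "block_summary",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LDPair:
    chrom: str
    pos_i: int
    pos_j: int
    r2: float
    dprime: float | None = None
    dprime_ci: tuple | None = None

    @property
    def distance(self) -> int:
        return self.pos_j - self.pos_i


@dataclass(frozen=True)
class HaplotypeBlock:
    chrom: str
    start: int  # position of the first SNP, 1-based
    end: int  # position of the last SNP, inclusive
    n_snps: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# Dosage r^2


def dosage_r2(g_i, g_j) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing calls (MISSING or nan) are removed pairwise.  Undefined (< 2
    complete pairs, or a locus monomorphic among them) returns nan.
    """
    x = np.asarray(g_i, dtype=float)
    y = np.asarray(g_j, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y) | (x == MISSING) | (y == MISSING))
    x, y = x[keep], y[keep]
    if x.size < 2:
        return float("nan")
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def pairwise_r2(dosage: np.ndarray) -> np.ndarray:
    """All-pairs dosage r^2 for a (samples x SNPs) matrix with missing calls.

    Uses cross-product algebra over the presence mask so that every pair is
    effectively computed on its pairwise-complete samples.  Entries with
    fewer than 2 complete pairs or zero variance are nan.
    """
    X = dosage.astype(float)
    M = (dosage != MISSING).astype(float)
    X0 = np.where(dosage == MISSING, 0.0, X)

    n = M.T @ M  # complete pairs per (i, j)
    s_i = X0.T @ M  # sum of x_i over samples complete for (i, j)
    s_j = s_i.T
    ss_i = (X0 * X0).T @ M
    ss_j = ss_i.T
    sxy = X0.T @ X0

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - s_i * s_j / n
        var_i = ss_i - s_i * s_i / n
        var_j = ss_j - s_j * s_j / n
        r2 = (cov * cov) / (var_i * var_j)
    r2[(n < 2) | ~np.isfinite(r2)] = np.nan
    return r2


def ld_decay(
    gm: GenotypeMatrix,
    pop_map: pd.DataFrame,
    max_dist_kb: float = 50.0,
    bin_width_kb: float = 1.0,
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Median pairwise r^2 by inter-SNP distance bin, per population.

    All intra-chromosomal SNP pairs at distance <= ``max_dist_kb`` are
    binned by distance; the median r^2 is reported per bin, with bins having
    fewer than ``min_pairs`` pairs flagged ``low_n``.
    """
    max_bp = max_dist_kb * 1000.0
    edges = np.arange(0.0, max_dist_kb + bin_width_kb, bin_width_kb)
    out = []
    for pop, grp in pop_map.groupby("population", sort=False):
        sub = gm.take_samples(list(grp["sample_id"]))
        dists, r2s = [], []
        for chrom, snp_grp in sub.snps.reset_index(drop=True).groupby("chrom", sort=False):
            idx = snp_grp.index.to_numpy()
            pos = snp_grp["pos"].to_numpy()
            if len(idx) < 2:
                continue
            r2 = pairwise_r2(sub.dosage[:, idx])
            d = np.abs(pos[:, None] - pos[None, :]).astype(float)
            iu = np.triu_indices(len(idx), k=1)
            keep = (d[iu] <= max_bp) & ~np.isnan(r2[iu])
            dists.append(d[iu][keep])
            r2s.append(r2[iu][keep])
        dists = np.concatenate(dists) if dists else np.empty(0)
        r2s = np.concatenate(r2s) if r2s else np.empty(0)
        which = np.clip(np.digitize(dists / 1000.0, edges) - 1, 0, len(edges) - 2)
        for b in range(len(edges) - 1):
            sel = which == b if dists.size else np.empty(0, dtype=bool)
            vals = r2s[sel] if dists.size else np.empty(0)
            out.append(
                {
                    "population": pop,
                    "bin_start_kb": edges[b],
                    "median_r2": float(np.median(vals)) if vals.size else np.nan,
                    "n_pairs": int(vals.size),
                    "low_n": bool(vals.size < min_pairs),
                }
            )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# EM haplotype frequencies and Gabriel-style D' confidence intervals


def _pair_counts(g_i, g_j) -> np.ndarray:
    """3x3 table of joint dosage counts over pairwise-complete samples."""
    x = np.asarray(g_i)
    y = np.asarray(g_j)
    keep = (x != MISSING) & (y != MISSING)
    x, y = x[keep], y[keep]
    counts = np.zeros((3, 3))
    for a, b in zip(x, y):
        counts[a, b] += 1
    return counts


def em_haplotype_freqs(
    g_i, g_j, tol: float = 1e-8, max_iter: int = 3000, return_loglik_trace: bool = False
):
    """Two-locus haplotype frequencies (f00, f01, f10, f11) by EM.

    Alleles are coded 0 = REF, 1 = ALT at both loci; f01 is the frequency of
    the haplotype carrying REF at the first locus and ALT at the second.
    Only the double heterozygote is phase-ambiguous; its gametes are split
    between the two phases in proportion to the current estimate of
    f00*f11 vs f01*f10.  Convergence is declared when no frequency moves by
    more than ``tol``; boundary solutions (a haplotype frequency heading to
    0) converge sublinearly, hence the generous ``max_iter``.
    """
    counts = _pair_counts(g_i, g_j)
    n = counts.sum()
    if n < 2:
        raise ValidationError("need at least 2 pairwise-complete samples")

    # unambiguous gamete counts: genotype (a, b) contributes known haplotypes
    # except for the (1, 1) double heterozygote
    base = np.zeros(4)  # order: 00, 01, 10, 11
    contrib = {
        (0, 0): [(0, 2)],
        (0, 1): [(0, 1), (1, 1)],
        (0, 2): [(1, 2)],
        (1, 0): [(0, 1), (2, 1)],
        (1, 2): [(1, 1), (3, 1)],
        (2, 0): [(2, 2)],
        (2, 1): [(2, 1), (3, 1)],
        (2, 2): [(3, 2)],
    }
    for (a, b), haps in contrib.items():
        for h, mult in haps:
            base[h] += counts[a, b] * mult
    n_dh = counts[1, 1]  # double heterozygotes

    f = np.full(4, 0.25)
    trace: list[float] = []
    for _ in range(max_iter):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        tot = cis + trans
        w = 0.5 if tot == 0 else cis / tot
        g = base.copy()
        g[0] += n_dh * w
        g[3] += n_dh * w
        g[1] += n_dh * (1 - w)
        g[2] += n_dh * (1 - w)
        f_new = g / g.sum()
        if return_loglik_trace:
            trace.append(_loglik(f_new, counts))
        converged = np.max(np.abs(f_new - f)) < tol
        f = f_new
        if converged:
            break
    else:
        logger.warning("EM did not converge in %d iterations", max_iter)
    out = tuple(float(v) for v in f)
    return (out, trace) if return_loglik_trace else out


_HAP_ALLELES = np.array([(0, 0), (0, 1), (1, 0), (1, 1)])


def _genotype_probs(f: np.ndarray) -> np.ndarray:
    """3x3 joint genotype probabilities from haplotype frequencies.

    ``f`` may be (4,) or (m, 4); returns (3, 3) or (m, 3, 3)."""
    f = np.asarray(f, dtype=float)
    one = f.ndim == 1
    f = np.atleast_2d(f)
    G = np.zeros((f.shape[0], 3, 3))
    for h1 in range(4):
        for h2 in range(4):
            a = _HAP_ALLELES[h1][0] + _HAP_ALLELES[h2][0]
            b = _HAP_ALLELES[h1][1] + _HAP_ALLELES[h2][1]
            G[:, a, b] += f[:, h1] * f[:, h2]
    return G[0] if one else G


def _loglik(f: np.ndarray, counts: np.ndarray) -> float:
    G = _genotype_probs(np.asarray(f))
    with np.errstate(divide="ignore"):
        lg = np.where(counts > 0, np.log(np.where(G > 0, G, 1e-300)), 0.0)
    return float((counts * lg).sum())


def dprime_point(f) -> float:
    """|D'| from haplotype frequencies (f00, f01, f10, f11)."""
    f00, f01, f10, f11 = f
    p = f00 + f01  # REF frequency at locus i
    q = f00 + f10  # REF frequency at locus j
    D = f00 - p * q
    if D >= 0:
        dmax = min(p * (1 - q), (1 - p) * q)
    else:
        dmax = min(p * q, (1 - p) * (1 - q))
    if dmax <= 0:
        return float("nan")
    return float(abs(D) / dmax)


def dprime_ci(
    g_i,
    g_j,
    confidence: float = 0.90,
    grid_step: float = 0.001,
    tol: float = 1e-8,
):
    """Gabriel-style |D'| estimate and confidence interval.

    The likelihood of the genotype data is evaluated on a |D'| grid over
    [0, 1] with allele frequencies fixed at their sample marginals and the
    sign of D fixed at the EM point estimate; the CI is read off the
    normalized cumulative likelihood at the (1-c)/2 and (1+c)/2 quantiles
    (5th and 95th percentiles for the default 90% interval).

    Returns (dprime, ci_low, ci_high); raises ValidationError when a locus
    is monomorphic among complete pairs (pair non-informative).
    """
    counts = _pair_counts(g_i, g_j)
    n = counts.sum()
    if n < 2:
        raise ValidationError("need at least 2 pairwise-complete samples")
    margin_i = counts.sum(axis=1)
    margin_j = counts.sum(axis=0)
    p = (2 * margin_i[0] + margin_i[1]) / (2 * n)  # REF freq, locus i
    q = (2 * margin_j[0] + margin_j[1]) / (2 * n)
    if p in (0.0, 1.0) or q in (0.0, 1.0):
        raise ValidationError("monomorphic locus: D' undefined")

    f_hat = em_haplotype_freqs(g_i, g_j, tol=tol)
    D_hat = f_hat[0] - (f_hat[0] + f_hat[1]) * (f_hat[0] + f_hat[2])
    sign = 1.0 if D_hat >= 0 else -1.0
    if sign > 0:
        dmax = min(p * (1 - q), (1 - p) * q)
    else:
        dmax = min(p * q, (1 - p) * (1 - q))

    dgrid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    D = sign * dgrid * dmax
    f = np.stack(
        [p * q + D, p * (1 - q) - D, (1 - p) * q - D, (1 - p) * (1 - q) + D], axis=1
    )
    f = np.clip(f, 0.0, 1.0)
    G = _genotype_probs(f)  # (m, 3, 3)
    with np.errstate(divide="ignore"):
        ll = np.einsum("ab,mab->m", counts, np.log(np.clip(G, 1e-300, None)))
    like = np.exp(ll - ll.max())
    cum = np.cumsum(like)
    cum /= cum[-1]
    lo_q = (1.0 - confidence) / 2.0
    hi_q = 1.0 - lo_q
    ci_low = float(dgrid[np.searchsorted(cum, lo_q)])
    ci_high = float(dgrid[np.searchsorted(cum, hi_q)])
    point = dprime_point(f_hat)
    return point, ci_low, ci_high


# ---------------------------------------------------------------------------
# Gabriel blocks


def _classify_pair(g_i, g_j, strong, recomb_high):
    """'strong' / 'recomb' / 'uninformative' per Gabriel CI rules."""
    try:
        _, lo, hi = dprime_ci(g_i, g_j)
    except ValidationError:
        return "uninformative"
    if lo >= strong[0] and hi >= strong[1]:
        return "strong"
    if hi < recomb_high:
        return "recomb"
    return "uninformative"


def gabriel_blocks(
    gm: GenotypeMatrix,
    samples: list[str] | None = None,
    maf: float = 0.07,
    max_kb: float = 200.0,
    strong: tuple = (0.70, 0.98),
    recomb_high: float = 0.90,
    informative_frac: float = 0.95,
) -> list[HaplotypeBlock]:
    """Detect Gabriel-style haplotype blocks in one population.

    Candidate spans of <= ``max_kb`` whose outermost SNP pair is in strong LD
    and in which at least ``informative_frac`` of informative inner pairs
    (strong or strong-recombination) are strong are ranked by bp span,
    longest first, and accepted greedily without overlap.  SNPs below the
    ``maf`` floor in this population are excluded from pair evaluation.
    """
    sub = gm if samples is None else gm.take_samples(samples)
    max_bp = max_kb * 1000.0
    blocks: list[HaplotypeBlock] = []
    for chrom, snp_grp in sub.snps.reset_index(drop=True).groupby("chrom", sort=False):
        cols = snp_grp.index.to_numpy()
        dose = sub.dosage[:, cols]
        pos = snp_grp["pos"].to_numpy()

        called = dose != MISSING
        with np.errstate(invalid="ignore", divide="ignore"):
            af = np.where(called, dose, 0).sum(axis=0) / (2.0 * called.sum(axis=0))
        keep = ~np.isnan(af) & (np.fmin(af, 1 - af) >= maf)
        dose = dose[:, keep]
        pos = pos[keep]
        m = len(pos)
        if m < 2:
            continue

        cls = {}

        def classify(i, j):
            if (i, j) not in cls:
                cls[(i, j)] = _classify_pair(dose[:, i], dose[:, j], strong, recomb_high)
            return cls[(i, j)]

        candidates = []
        for i in range(m - 1):
            for j in range(i + 1, m):
                span = pos[j] - pos[i]
                if span > max_bp:
                    break
                if classify(i, j) != "strong":
                    continue
                n_strong = n_inform = 0
                for a in range(i, j + 1):
                    for b in range(a + 1, j + 1):
                        c = classify(a, b)
                        if c == "strong":
                            n_strong += 1
                            n_inform += 1
                        elif c == "recomb":
                            n_inform += 1
                if n_inform == 0 or n_strong / n_inform < informative_frac:
                    continue
                candidates.append((span, j - i + 1, i, j))

        candidates.sort(key=lambda t: (-t[0], -t[1], t[2]))
        used = np.zeros(m, dtype=bool)
        for span, _, i, j in candidates:
            if used[i : j + 1].any():
                continue
            used[i : j + 1] = True
            blocks.append(
                HaplotypeBlock(chrom=chrom, start=int(pos[i]), end=int(pos[j]), n_snps=j - i + 1)
            )
    blocks.sort(key=lambda b: (b.chrom, b.start))
    return blocks


def block_summary(blocks_by_pop: dict) -> pd.DataFrame:
    """Per-population block count and mean length (kb)."""
    rows = []
    for pop, blocks in blocks_by_pop.items():
        lengths = [b.length / 1000.0 for b in blocks]
        rows.append(
            {
                "population": pop,
                "n_blocks": len(blocks),
                "mean_length_kb": float(np.mean(lengths)) if lengths else np.nan,
            }
        )
    return pd.DataFrame(rows)


def blocks_frame(blocks_by_pop: dict) -> pd.DataFrame:
    """Flatten per-population block lists into one table."""
    rows = []
    for pop, blocks in blocks_by_pop.items():
        for b in blocks:
            rows.append(
                {
                    "population": pop,
                    "chrom": b.chrom,
                    "start": b.start,
                    "end": b.end,
                    "n_snps": b.n_snps,
                    "length_kb": b.length / 1000.0,
                }
            )
    return pd.DataFrame(
        rows, columns=["population", "chrom", "start", "end", "n_snps", "length_kb"]
    )
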