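"""Wright-Fisher drift null, empirical p-values, FDR control and the genome scan.

The null model for per-SNP allele-frequency change is pure binomial drift:
starting from the observed initial frequency, 2*Ne gene copies are resampled
for a fixed number of generation transitions (default Ne=16, 8 transitions,
i.e. generation 1 -> 9), with equal fitness for every individual.  Final
frequencies are pre-simulated 10,000-fold on a 0.01 grid of initial
frequencies ("drift bank"); the empirical p-value of an observed change is
the tail proportion of simulated finals at least as extreme as the observed
final, in the direction of the observed change.  Benjamini-Hochberg controls
the FDR within each population pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "DriftBank",
    "wright_fisher_final_af",
    "build_drift_bank",
    "empirical_pvalue",
    "delta_h",
    "bh_fdr",
    "scan_population",
    "scan_all_pairs",
    "intersect_significant",
    "POPULATION_PAIRS",
]

logger = logging.getLogger(__name__)

#: (label, initial population, final population) for the four generation-1 ->
#: generation-9 comparisons: two treatments x two replicates.
POPULATION_PAIRS = (
    ("bumblebee_A", "A1", "B9A"),
    ("bumblebee_B", "B1", "B9B"),
    ("control_A", "A1", "C9A"),
    ("control_B", "B1", "C9B"),
)


def wright_fisher_final_af(p0, ne: int = 16, transitions: int = 8, rng=None, size=None):
    """Final allele frequency after neutral Wright-Fisher drift.

    Repeated binomial resampling of ``2*ne`` gene copies for ``transitions``
    generations, starting at frequency ``p0``.  Returns a scalar when ``p0``
    is scalar and ``size`` is None, else an array.
    """
    p0 = np.asarray(p0, dtype=float)
    if np.any((p0 < 0) | (p0 > 1)):
        raise ValidationError("initial frequency must be in [0, 1]")
    if ne < 1:
        raise ValidationError("ne must be >= 1")
    if transitions < 1:
        raise ValidationError("transitions must be >= 1")
    rng = np.random.default_rng(rng)
    copies = 2 * ne
    scalar = p0.ndim == 0 and size is None
    p = np.broadcast_to(p0, size if size is not None else p0.shape).astype(float).copy()
    for _ in range(transitions):
        p = np.asarray(rng.binomial(copies, p)) / copies
    return float(p) if scalar else p


@dataclass
class DriftBank:
    """Pre-simulated final-frequency distributions on an initial-AF grid.

    ``sims[i]`` holds ``n_sim`` simulated final frequencies for initial
    frequency ``grid[i]``.
    """

    grid: np.ndarray
    sims: np.ndarray
    ne: int = 16
    transitions: int = 8
    seed: int | None = None
    _sorted: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_sim(self) -> int:
        return self.sims.shape[1]

    @property
    def grid_step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def sorted_sims(self) -> np.ndarray:
        if self._sorted is None:
            self._sorted = np.sort(self.sims, axis=1)
        return self._sorted

    def grid_index(self, af: np.ndarray) -> np.ndarray:
        """Nearest grid point, ties toward the lower grid value."""
        x = np.asarray(af, dtype=float) / self.grid_step
        idx = np.floor(x + 0.5).astype(int)
        halfway = np.isclose(x + 0.5, np.round(x + 0.5)) & ~np.isclose(x, np.round(x))
        idx = np.where(halfway, idx - 1, idx)
        return np.clip(idx, 0, len(self.grid) - 1)

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            grid=self.grid,
            sims=self.sims,
            meta=np.array([self.ne, self.transitions, -1 if self.seed is None else self.seed]),
        )

    @classmethod
    def load(cls, path) -> "DriftBank":
        with np.load(path) as z:
            ne, transitions, seed = (int(v) for v in z["meta"])
            return cls(
                grid=z["grid"],
                sims=z["sims"],
                ne=ne,
                transitions=transitions,
                seed=None if seed < 0 else seed,
            )


def build_drift_bank(
    grid_step: float = 0.01,
    n_sim: int = 10_000,
    ne: int = 16,
    transitions: int = 8,
    seed: int = 0,
) -> DriftBank:
    """Simulate the drift null for every initial frequency on the grid."""
    if n_sim < 1:
        raise ValidationError("n_sim must be >= 1")
    n_points = round(1.0 / grid_step) + 1
    if not np.isclose((n_points - 1) * grid_step, 1.0):
        raise ValidationError("grid_step must divide 1 evenly")
    grid = np.round(np.linspace(0.0, 1.0, n_points), 10)
    rng = np.random.default_rng(np.random.SeedSequence([seed, ne, transitions]))
    sims = np.empty((n_points, n_sim), dtype=np.float32)
    for i, p0 in enumerate(grid):
        sims[i] = wright_fisher_final_af(p0, ne=ne, transitions=transitions, rng=rng, size=n_sim)
    return DriftBank(grid=grid, sims=sims, ne=ne, transitions=transitions, seed=seed)


def delta_h(af_initial, af_final):
    """Allele-frequency change between first and final generation."""
    return np.asarray(af_final, dtype=float) - np.asarray(af_initial, dtype=float)


def empirical_pvalue(af_initial, af_final, bank: DriftBank, literal_tails: bool = False):
    """Empirical drift p-value of an observed frequency change.

    The initial frequency selects the nearest bank grid point.  With the
    default (tail-consistent) convention, a decrease counts simulated finals
    <= the observed final and an increase counts simulated finals >= it;
    no change gives p = 1.  ``literal_tails=True`` swaps the two
    inequalities, reproducing a published formulation in which the
    decrease case is printed with ">=".
    """
    a0 = np.atleast_1d(np.asarray(af_initial, dtype=float))
    a1 = np.atleast_1d(np.asarray(af_final, dtype=float))
    if a0.shape != a1.shape:
        raise ValidationError("af_initial and af_final must have the same shape")
    ok = ~(np.isnan(a0) | np.isnan(a1))
    if np.any((a0[ok] < 0) | (a0[ok] > 1) | (a1[ok] < 0) | (a1[ok] > 1)):
        raise ValidationError("allele frequencies must be in [0, 1]")

    p = np.full(a0.shape, np.nan)
    idx = np.zeros(a0.shape, dtype=int)
    idx[ok] = bank.grid_index(a0[ok])
    srt = bank.sorted_sims()
    n = bank.n_sim

    dec = ok & (a0 > a1)
    inc = ok & (a0 < a1)
    same = ok & (a0 == a1)
    if literal_tails:
        lower, upper = inc, dec
    else:
        lower, upper = dec, inc

    # lower tail: count sims <= observed final
    rows = idx[lower]
    p[lower] = np.array(
        [np.searchsorted(srt[r], x, side="right") for r, x in zip(rows, a1[lower])]
    ) / n
    # upper tail: count sims >= observed final
    rows = idx[upper]
    p[upper] = np.array(
        [n - np.searchsorted(srt[r], x, side="left") for r, x in zip(rows, a1[upper])]
    ) / n
    p[same] = 1.0
    if np.isscalar(af_initial) and np.isscalar(af_final):
        return float(p[0])
    return p


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def scan_population(
    af_table: pd.DataFrame,
    bank: DriftBank,
    initial_pop: str,
    final_pop: str,
    fdr: float = 0.05,
    strong_threshold: float = 0.5,
    literal_tails: bool = False,
    label: str | None = None,
) -> pd.DataFrame:
    """Drift scan of one generation-1 -> generation-9 population pair.

    Joins initial and final reference-allele frequencies per SNP, computes
    delta_h, the empirical drift p-value and BH q-value (FDR within this
    pair), and flags significant (q < fdr) and strong (|delta_h| >
    strong_threshold) changes.  SNPs lacking either frequency are skipped
    and counted in the log.
    """
    cols = ["chrom", "pos", "af_ref"]
    ini = af_table.loc[af_table["population"] == initial_pop, cols].rename(
        columns={"af_ref": "af_initial"}
    )
    fin = af_table.loc[af_table["population"] == final_pop, cols].rename(
        columns={"af_ref": "af_final"}
    )
    if ini.empty or fin.empty:
        raise ValidationError(
            f"no allele frequencies for pair ({initial_pop}, {final_pop})"
        )
    df = ini.merge(fin, on=["chrom", "pos"], how="inner")
    if df.empty:
        raise ValidationError("no overlapping SNPs between the two populations")
    n_before = len(df)
    df = df.dropna(subset=["af_initial", "af_final"]).reset_index(drop=True)
    n_skipped = n_before - len(df)
    if n_skipped:
        logger.info(
            "scan %s->%s: skipped %d SNPs with missing AF", initial_pop, final_pop, n_skipped
        )
    df["population"] = label or f"{initial_pop}->{final_pop}"
    df["delta_h"] = delta_h(df["af_initial"], df["af_final"])
    df["pvalue"] = empirical_pvalue(
        df["af_initial"].to_numpy(), df["af_final"].to_numpy(), bank, literal_tails
    )
    df["qvalue"] = bh_fdr(df["pvalue"].to_numpy())
    df["significant"] = df["qvalue"] < fdr
    df["strong"] = df["delta_h"].abs() > strong_threshold
    df.attrs["n_skipped"] = n_skipped
    return df


def scan_all_pairs(
    af_table: pd.DataFrame,
    bank: DriftBank,
    pairs=POPULATION_PAIRS,
    fdr: float = 0.05,
    **kwargs,
) -> pd.DataFrame:
    """Run :func:`scan_population` for each (label, initial, final) pair and
    concatenate the records; FDR is controlled separately within each pair."""
    frames = [
        scan_population(af_table, bank, ini, fin, fdr=fdr, label=label, **kwargs)
        for label, ini, fin in pairs
    ]
    return pd.concat(frames, ignore_index=True)


def intersect_significant(sets: dict) -> pd.DataFrame:
    """Exclusive (UpSet-style) intersection counts of named SNP sets.

    Each element of the union is assigned to exactly one combination: the
    full set of names that contain it.  Returns a DataFrame with columns
    ``members`` (sorted '+'-joined names), ``degree`` and ``count``; the
    counts partition the union.
    """
    if not sets:
        raise ValidationError("at least one named set is required")
    names = sorted(sets)
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(set(sets[c]) for c in combo))
            outside = set.union(
                set(), *(set(sets[c]) for c in names if c not in combo)
            )
            rows.append(
                {
                    "members": "+".join(combo),
                    "degree": r,
                    "count": len(inside - outside),
                }
            )
    return pd.DataFrame(rows)
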