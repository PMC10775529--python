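"""Forward simulator of the nine-generation pollinator experimental-evolution design.

Emulates the structure of the greenhouse experiment: for each of two
replicates, a founder population of full-sib families gives rise to a first
generation of 36 plants; from that shared first generation two treatments
evolve independently for eight further transitions — a control treatment in
which every plant contributes equally (random hand pollination), and a
"bumblebee" treatment in which a plant's chance of mothering/fathering seeds
is proportional to a multiplicative fecundity (1+s) per ALT allele at each
selected locus.  A tenth generation is produced by crossing replicates within
a treatment.  From every output population a fixed number of individuals
(default 32 of 36) is "sequenced": dosages are extracted, per-call GQ/DP
fields are drawn, and calls are masked at a configurable missing rate.

Plants are obligate outcrossers (genetic self-incompatibility): an
individual never fathers its own seeds.

The simulator returns genotype matrices per population plus a ground-truth
table of selected loci, so every downstream stage (filters, drift scan, LD,
blocks, PCA) can be tested against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, ValidationError
from .variant_io import MISSING, GenotypeMatrix, write_vcf as _write_vcf_matrix

__all__ = [
    "SimulationParams",
    "Haplotypes",
    "SimulatedStudy",
    "simulate_generation",
    "simulate_experiment",
    "inter_replicate_cross",
    "sequence_population",
    "write_vcf",
]

_NUCS = np.array(list("ACGT"))

#: the eight sequenced populations, in output order
POPULATIONS = ("A1", "B1", "C9A", "C9B", "B9A", "B9B", "C10", "B10")


def _default_chromosomes() -> tuple:
    # ten chromosomes, ~283 Mb genome
    return tuple((f"A{i:02d}", 28_300_000) for i in range(1, 11))


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the experimental-evolution simulator.

    The defaults mirror the design being emulated: 36 plants per replicate
    per generation, nine generations, 32 individuals sequenced per
    population, ten chromosomes, and a genome-wide SNP count matching the
    filtered marker set of the study design (4,713 biallelic SNPs).
    """

    n_snps: int = 4713
    chromosomes: tuple = field(default_factory=_default_chromosomes)
    n_founder_families: int = 108
    n_plants: int = 36
    n_generations: int = 9
    n_sequenced: int = 32
    recomb_fraction: float = 0.1
    selected_loci: tuple = ()  # ((locus_index, s), ...)
    founder_af_range: tuple = (0.1, 0.9)
    #: number of distinct ancestral segment-haplotypes per founder LD
    #: segment; None draws every founder allele independently (linkage
    #: equilibrium).  A small value gives the base population short-range
    #: standing LD: within a segment only founder_pool_size allele
    #: combinations circulate, while segments combine freely.
    founder_pool_size: int | None = None
    #: number of adjacent loci forming one founder LD segment (sets the
    #: length scale of the founders' haplotype blocks; only used when
    #: founder_pool_size is set).
    founder_segment_loci: int = 8
    #: founder ALT frequency at the selected loci; None uses the global
    #: founder_af_range.  Setting it low (e.g. 0.1) models selection on
    #: initially rare standing variants (soft sweeps reach intermediate
    #: frequency within nine generations).
    selected_founder_af: float | None = None
    missing_rate: float = 0.02
    gq_beta: tuple = (8.0, 2.0, 60.0)  # (a, b, scale) of a discretised beta
    dp_nbinom: tuple = (30.0, 10.0)  # (mean, shape) of a negative binomial
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 2:
            raise ValidationError("n_snps must be >= 2")
        if not self.chromosomes:
            raise ValidationError("at least one chromosome is required")
        if self.n_sequenced > self.n_plants:
            raise ValidationError("n_sequenced must be <= n_plants")
        if not 0.0 < self.recomb_fraction <= 0.5:
            raise ValidationError("recomb_fraction must be in (0, 0.5]")
        lo, hi = self.founder_af_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValidationError("founder AFs must lie strictly inside (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must be in [0, 1)")
        idx = [i for i, _ in self.selected_loci]
        if len(set(idx)) != len(idx):
            raise ValidationError("selected locus indices must be unique")
        if any(i < 0 or i >= self.n_snps for i in idx):
            raise ValidationError("selected locus index out of range")
        if any(s < 0 for _, s in self.selected_loci):
            raise ValidationError("selection coefficients must be >= 0")
        if self.selected_founder_af is not None and not (
            0.0 < self.selected_founder_af < 1.0
        ):
            raise ValidationError("selected_founder_af must be in (0, 1)")
        if self.n_generations < 1:
            raise ValidationError("n_generations must be >= 1")


@dataclass
class Haplotypes:
    """Phased genotypes of one plant population.

    ``hap`` has shape ``(n_individuals, 2, n_snps)`` with 0 = REF, 1 = ALT.
    ``snps`` is the shared SNP table (chrom, pos, ref, alt).
    """

    hap: np.ndarray
    snps: pd.DataFrame

    @property
    def n_individuals(self) -> int:
        return self.hap.shape[0]

    @property
    def n_snps(self) -> int:
        return self.hap.shape[2]

    def dosage(self) -> np.ndarray:
        return self.hap.sum(axis=1).astype(np.int8)

    def alt_af(self) -> np.ndarray:
        return self.hap.mean(axis=(0, 1))


def _switch_prob(snps: pd.DataFrame, recomb_fraction: float) -> np.ndarray:
    """Per-adjacent-locus-pair probability that a gamete switches haplotype.

    ``recomb_fraction`` within a chromosome, free recombination (0.5) across
    chromosome boundaries.
    """
    chrom = snps["chrom"].to_numpy()
    same = chrom[1:] == chrom[:-1]
    return np.where(same, recomb_fraction, 0.5)


def _make_gametes(parent_hap: np.ndarray, switch_p: np.ndarray, rng) -> np.ndarray:
    """One recombinant gamete per row of ``parent_hap`` ((n, 2, L) -> (n, L))."""
    n, _, L = parent_hap.shape
    start = rng.integers(0, 2, size=n)
    if L > 1:
        cross = rng.random((n, L - 1)) < switch_p
        sel = (start[:, None] + np.concatenate(
            [np.zeros((n, 1), dtype=np.int64), np.cumsum(cross, axis=1)], axis=1
        )) % 2
    else:
        sel = start[:, None]
    return parent_hap[np.arange(n)[:, None], sel, np.arange(L)[None, :]]


def _sample_parents(weights: np.ndarray, n_offspring: int, rng):
    """Sample (mother, father) index pairs proportional to fitness weights,
    enforcing mother != father (self-incompatibility)."""
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValidationError("fitness weights must be nonnegative")
    if w.size < 2:
        raise DesignError("at least two parents are required (obligate outcrossing)")
    if not w.sum() > 0:
        raise DesignError("fitness weights must not all be zero")
    p = w / w.sum()
    mothers = rng.choice(w.size, size=n_offspring, p=p)
    fathers = np.empty(n_offspring, dtype=np.int64)
    for k, m in enumerate(mothers):
        q = p.copy()
        q[m] = 0.0
        tot = q.sum()
        if tot <= 0:
            # the mother carries all fitness mass; any other plant fathers
            q[:] = 1.0
            q[m] = 0.0
            tot = q.sum()
        fathers[k] = rng.choice(w.size, p=q / tot)
    return mothers, fathers


def simulate_generation(
    parents: Haplotypes,
    fitness_weights: np.ndarray,
    n_offspring: int,
    recomb_fraction: float,
    rng: np.random.Generator,
) -> Haplotypes:
    """Produce one offspring generation by fecundity-weighted outcrossing.

    Each offspring draws a mother and a distinct father with probability
    proportional to ``fitness_weights`` (the per-plant expected seed
    contribution), and receives one recombinant gamete from each.
    """
    mothers, fathers = _sample_parents(fitness_weights, n_offspring, rng)
    switch_p = _switch_prob(parents.snps, recomb_fraction)
    egg = _make_gametes(parents.hap[mothers], switch_p, rng)
    sperm = _make_gametes(parents.hap[fathers], switch_p, rng)
    return Haplotypes(hap=np.stack([egg, sperm], axis=1), snps=parents.snps)


def inter_replicate_cross(
    pop_a: Haplotypes,
    pop_b: Haplotypes,
    n_offspring: int,
    rng: np.random.Generator,
    recomb_fraction: float = 0.5,
) -> Haplotypes:
    """Cross two replicate populations: every offspring has one parent from
    each replicate, with donors and receivers assigned uniformly at random."""
    if pop_a.n_snps != pop_b.n_snps or not pop_a.snps[["chrom", "pos"]].equals(
        pop_b.snps[["chrom", "pos"]]
    ):
        raise ValidationError("replicates must share an identical SNP set")
    ma = rng.integers(0, pop_a.n_individuals, size=n_offspring)
    mb = rng.integers(0, pop_b.n_individuals, size=n_offspring)
    switch_p = _switch_prob(pop_a.snps, recomb_fraction)
    ga = _make_gametes(pop_a.hap[ma], switch_p, rng)
    gb = _make_gametes(pop_b.hap[mb], switch_p, rng)
    return Haplotypes(hap=np.stack([ga, gb], axis=1), snps=pop_a.snps)


def _selection_weights(pop: Haplotypes, selected: tuple) -> np.ndarray:
    """Multiplicative genic fecundity: w_i = prod (1+s)^(ALT count at locus)."""
    w = np.ones(pop.n_individuals)
    if selected:
        dose = pop.dosage()
        for locus, s in selected:
            w *= (1.0 + s) ** dose[:, locus].astype(float)
    return w


def _founder_population(
    params: SimulationParams, snps: pd.DataFrame, alt_af: np.ndarray, rng
) -> Haplotypes:
    """First generation of a replicate, built from full-sib founder families.

    Each family has two unrelated diploid parents drawn from the per-locus
    founder allele frequencies; family members are recombinant full sibs.
    With at least as many families as plants every plant comes from its own
    family, i.e. founders are effectively unrelated.
    """
    k = max(1, min(params.n_founder_families, params.n_plants))
    fam_of = rng.permutation(np.arange(params.n_plants) % k)
    if params.founder_pool_size is None:
        # every founder haplotype independent: linkage equilibrium
        parent_hap = rng.random((k, 2, 2, params.n_snps)) < alt_af
        parent_hap = parent_hap.astype(np.int8)  # (family, parent, hap, L)
    else:
        if params.founder_pool_size < 2:
            raise ValidationError("founder_pool_size must be >= 2")
        parent_hap = _segmented_haplotypes(
            (k, 2, 2),
            snps,
            alt_af,
            params.founder_pool_size,
            params.founder_segment_loci,
            rng,
        )
    switch_p = _switch_prob(snps, params.recomb_fraction)
    egg = _make_gametes(parent_hap[fam_of, 0], switch_p, rng)
    sperm = _make_gametes(parent_hap[fam_of, 1], switch_p, rng)
    return Haplotypes(hap=np.stack([egg, sperm], axis=1), snps=snps)


def _segmented_haplotypes(shape, snps, alt_af, pool_size, segment_loci, rng):
    """Founder haplotypes built from short ancestral segments.

    Each chromosome is cut into consecutive segments of ``segment_loci``
    markers; for every segment only ``pool_size`` distinct segment
    haplotypes exist (drawn per locus from the founder allele frequencies),
    and every founder chromosome picks one variant per segment
    independently.  Within-segment LD is strong (few allele combinations),
    between-segment LD absent: the base population carries short haplotype
    blocks in linkage equilibrium with one another.
    """
    L = len(snps)
    chrom = snps["chrom"].to_numpy()
    # global segment ids: restart at chromosome boundaries
    seg = np.zeros(L, dtype=np.int64)
    seg_id = 0
    count = 0
    for l in range(1, L):
        count += 1
        if chrom[l] != chrom[l - 1] or count >= segment_loci:
            seg_id += 1
            count = 0
        seg[l] = seg_id
    n_seg = seg_id + 1
    pool = (rng.random((pool_size, L)) < alt_af).astype(np.int8)
    n_hap = int(np.prod(shape))
    pick = rng.integers(0, pool_size, size=(n_hap, n_seg))
    hap = pool[pick[:, seg], np.arange(L)[None, :]]
    return hap.reshape(*shape, L)


def sequence_population(
    pop: Haplotypes, params: SimulationParams, sample_prefix: str, rng
) -> GenotypeMatrix:
    """Draw ``n_sequenced`` plants without replacement and emit a genotype
    matrix with simulated per-call GQ/DP and missing calls."""
    rows = rng.choice(pop.n_individuals, size=params.n_sequenced, replace=False)
    rows.sort()
    dose = pop.hap[rows].sum(axis=1).astype(np.int8)
    shape = dose.shape
    a, b, scale = params.gq_beta
    gq = np.round(rng.beta(a, b, size=shape) * scale)
    mean, k = params.dp_nbinom
    dp = rng.negative_binomial(k, k / (k + mean), size=shape).astype(float)
    if params.missing_rate > 0:
        miss = rng.random(shape) < params.missing_rate
        dose = dose.copy()
        dose[miss] = MISSING
        gq[miss] = np.nan
        dp[miss] = np.nan
    ids = [f"{sample_prefix}_{i:03d}" for i in range(1, params.n_sequenced + 1)]
    return GenotypeMatrix(dosage=dose, snps=pop.snps, sample_ids=ids, gq=gq, dp=dp)


@dataclass
class SimulatedStudy:
    """Outputs of one simulated experiment: the eight sequenced populations,
    the selected-locus truth table, per-generation ALT-AF trajectories, and
    the sample->population map."""

    populations: dict
    truth: pd.DataFrame
    trajectories: pd.DataFrame
    sample_map: pd.DataFrame
    params: SimulationParams


def _snp_table(params: SimulationParams, rng) -> pd.DataFrame:
    lengths = np.array([l for _, l in params.chromosomes], dtype=float)
    counts = np.floor(params.n_snps * lengths / lengths.sum()).astype(int)
    for i in range(params.n_snps - counts.sum()):
        counts[i % len(counts)] += 1
    rows = []
    for (name, length), c in zip(params.chromosomes, counts):
        if c > length:
            raise ValidationError(f"more SNPs than base pairs on {name}")
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=c, replace=False))
        for p in pos:
            rows.append((name, int(p)))
    snps = pd.DataFrame(rows, columns=["chrom", "pos"])
    ref = rng.integers(0, 4, size=len(snps))
    alt = (ref + rng.integers(1, 4, size=len(snps))) % 4
    snps["ref"] = _NUCS[ref]
    snps["alt"] = _NUCS[alt]
    return snps


def simulate_experiment(params: SimulationParams) -> SimulatedStudy:
    """Run the full two-replicate, two-treatment, nine-generation design.

    Control and bumblebee treatments branch from the same first generation
    within a replicate; the tenth generation crosses replicates within each
    treatment.  Fully reproducible from ``params.seed``.
    """
    params.validate()
    root = np.random.default_rng(np.random.SeedSequence([params.seed, 20240109]))
    snps = _snp_table(params, root)

    lo, hi = params.founder_af_range
    traj_rows = []
    populations: dict = {}
    gen9: dict = {}

    def record(rep, treatment, gen, pop):
        af = pop.alt_af()
        traj_rows.append(
            pd.DataFrame(
                {
                    "replicate": rep,
                    "treatment": treatment,
                    "generation": gen,
                    "locus": np.arange(pop.n_snps),
                    "af_alt": af,
                }
            )
        )

    for rep in ("A", "B"):
        rng = np.random.default_rng(
            np.random.SeedSequence([params.seed, 1, ord(rep)])
        )
        founder_af = rng.uniform(lo, hi, size=params.n_snps)
        if params.selected_founder_af is not None:
            for locus, _ in params.selected_loci:
                founder_af[locus] = params.selected_founder_af
        gen1 = _founder_population(params, snps, founder_af, rng)
        record(rep, "shared", 1, gen1)
        populations["A1" if rep == "A" else "B1"] = sequence_population(
            gen1, params, ("A1" if rep == "A" else "B1"), rng
        )
        for t_idx, (treatment, prefix) in enumerate(
            (("control", "C9"), ("bumblebee", "B9"))
        ):
            trng = np.random.default_rng(
                np.random.SeedSequence([params.seed, 2, ord(rep), t_idx])
            )
            pop = gen1
            selected = params.selected_loci if treatment == "bumblebee" else ()
            for gen in range(2, params.n_generations + 1):
                weights = _selection_weights(pop, selected)
                pop = simulate_generation(
                    pop, weights, params.n_plants, params.recomb_fraction, trng
                )
                record(rep, treatment, gen, pop)
            name = f"{prefix}{rep}"
            gen9[(treatment, rep)] = pop
            populations[name] = sequence_population(pop, params, name, trng)

    for t_idx, (treatment, name) in enumerate(
        (("control", "C10"), ("bumblebee", "B10"))
    ):
        xrng = np.random.default_rng(
            np.random.SeedSequence([params.seed, 3, t_idx])
        )
        f1 = inter_replicate_cross(
            gen9[(treatment, "A")],
            gen9[(treatment, "B")],
            params.n_plants,
            xrng,
            recomb_fraction=params.recomb_fraction,
        )
        record("AxB", treatment, params.n_generations + 1, f1)
        populations[name] = sequence_population(f1, params, name, xrng)

    truth = pd.DataFrame(
        [
            {
                "locus": i,
                "chrom": snps.iloc[i]["chrom"],
                "pos": snps.iloc[i]["pos"],
                "s": s,
                "expected_direction": "alt_up_in_bumblebee",
            }
            for i, s in params.selected_loci
        ],
        columns=["locus", "chrom", "pos", "s", "expected_direction"],
    )

    pop_meta = {
        "A1": (1, "shared", "A"),
        "B1": (1, "shared", "B"),
        "C9A": (9, "control", "A"),
        "C9B": (9, "control", "B"),
        "B9A": (9, "bumblebee", "A"),
        "B9B": (9, "bumblebee", "B"),
        "C10": (10, "control", "AxB"),
        "B10": (10, "bumblebee", "AxB"),
    }
    map_rows = []
    for name in POPULATIONS:
        gen, treatment, rep = pop_meta[name]
        for sid in populations[name].sample_ids:
            map_rows.append((sid, name, gen, treatment, rep))
    sample_map = pd.DataFrame(
        map_rows, columns=["sample_id", "population", "generation", "treatment", "replicate"]
    )

    return SimulatedStudy(
        populations={name: populations[name] for name in POPULATIONS},
        truth=truth,
        trajectories=pd.concat(traj_rows, ignore_index=True),
        sample_map=sample_map,
        params=params,
    )


def merged_matrix(study: SimulatedStudy) -> GenotypeMatrix:
    """Concatenate the eight sequenced populations into one genotype matrix."""
    mats = list(study.populations.values())
    return GenotypeMatrix(
        dosage=np.vstack([m.dosage for m in mats]),
        snps=mats[0].snps,
        sample_ids=[s for m in mats for s in m.sample_ids],
        gq=np.vstack([m.gq for m in mats]),
        dp=np.vstack([m.dp for m in mats]),
    )


def write_vcf(study: SimulatedStudy, outdir) -> dict:
    """Write the merged VCF, the sample map TSV and the truth TSV.

    Returns the paths of the three files."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    vcf_path = out / "simulated.vcf"
    gm = merged_matrix(study)
    contig_lengths = dict(study.params.chromosomes)
    _write_vcf_matrix(gm, vcf_path, contig_lengths=contig_lengths)
    map_path = out / "samples.tsv"
    study.sample_map.to_csv(map_path, sep="\t", index=False)
    truth_path = out / "truth.tsv"
    study.truth.to_csv(truth_path, sep="\t", index=False)
    return {"vcf": vcf_path, "sample_map": map_path, "truth": truth_path}
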