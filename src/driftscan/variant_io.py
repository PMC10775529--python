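"""VCF input/output, the site-filter cascade, and per-population allele frequencies.

Genotypes are stored as ALT-dosage matrices (samples x SNPs, values 0/1/2,
-1 for a missing call) together with per-SNP coordinates and, when present,
per-call genotype quality (GQ) and read depth (DP).

The filter cascade mirrors a standard vcftools-style quality trimming of a
genotyping-by-sequencing call set: restriction to assembled chromosomes,
per-site missingness, biallelic sites only, minimum mean genotype quality,
maximum mean depth, and a pooled minor-allele-frequency floor, applied in
that order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import ValidationError

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "FilterConfig",
    "FilterReport",
    "read_vcf",
    "read_sample_map",
    "write_vcf",
    "apply_site_filters",
    "minimum_calls",
    "allele_frequencies",
    "pooled_alt_frequency",
    "marker_density",
]


@dataclass
class GenotypeMatrix:
    """Diploid ALT-allele dosages for a set of samples at a set of SNPs.

    Attributes
    ----------
    dosage
        ``(n_samples, n_snps)`` int8 array; entries in {0, 1, 2} count ALT
        alleles, ``MISSING`` (-1) marks an uncalled genotype.
    snps
        Per-SNP table with columns ``chrom``, ``pos`` (1-based), ``ref``,
        ``alt`` (comma-joined when multiallelic).
    sample_ids
        Sample names, aligned with the dosage rows.
    gq, dp
        Optional per-call genotype quality / depth, same shape as ``dosage``,
        ``nan`` where the call is missing.
    """

    dosage: np.ndarray
    snps: pd.DataFrame
    sample_ids: list[str]
    gq: np.ndarray | None = None
    dp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValidationError("dosage must be 2-D (samples x SNPs)")
        if self.dosage.shape[0] != len(self.sample_ids):
            raise ValidationError("sample_ids length does not match dosage rows")
        if self.dosage.shape[1] != len(self.snps):
            raise ValidationError("snps table length does not match dosage columns")
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValidationError("dosage entries must be in {0,1,2} or missing")
        if len(self.snps) and (self.snps["pos"].to_numpy() < 1).any():
            raise ValidationError("SNP positions must be 1-based (>= 1)")
        for _, grp in self.snps.groupby("chrom", sort=False):
            p = grp["pos"].to_numpy()
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValidationError(
                    "SNPs must be strictly increasing by position within a chromosome"
                )

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def take_snps(self, mask_or_index: np.ndarray) -> "GenotypeMatrix":
        """Subset SNP columns (boolean mask or integer index), keeping order."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            dosage=self.dosage[:, idx],
            snps=self.snps.iloc[idx].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
            gq=None if self.gq is None else self.gq[:, idx],
            dp=None if self.dp is None else self.dp[:, idx],
        )

    def take_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        """Subset to the given samples, in the given order."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise ValidationError(f"unknown samples: {missing[:5]}")
        rows = [lookup[s] for s in sample_ids]
        return GenotypeMatrix(
            dosage=self.dosage[rows],
            snps=self.snps,
            sample_ids=list(sample_ids),
            gq=None if self.gq is None else self.gq[rows],
            dp=None if self.dp is None else self.dp[rows],
        )


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the site-filter cascade.

    Defaults follow common vcftools practice for GBS data: drop sites missing
    in more than 5% of individuals, keep biallelic SNPs with mean GQ >= 15 and
    mean depth <= 100, and drop minor-allele frequencies below 0.1 (pooled
    across all samples).
    """

    max_missing_frac: float = 0.05
    biallelic_only: bool = True
    min_mean_gq: float = 15.0
    max_mean_dp: float = 100.0
    min_maf: float = 0.1
    chromosomes: tuple[str, ...] | None = None
    #: keep sites whose mean DP exceeds the bound instead (the inverted
    #: reading of a "removed ... less or equal" phrasing); off by default.
    invert_mean_dp: bool = False
    #: missingness boundary semantics: "tool" keeps a site when the fraction
    #: of present calls is >= 1 - max_missing_frac (vcftools --max-missing),
    #: "floor" keeps it when calls >= floor((1-max_missing_frac) * n).
    missing_semantics: str = "tool"
    #: vcftools --minGQ semantics: mask individual calls with GQ below
    #: min_mean_gq (before the missingness filter) instead of filtering
    #: sites on their mean GQ.
    gq_mask_calls: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_frac <= 1.0:
            raise ValidationError("max_missing_frac must be in [0, 1]")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValidationError("min_maf must be in [0, 0.5]")
        if self.missing_semantics not in ("tool", "floor"):
            raise ValidationError("missing_semantics must be 'tool' or 'floor'")


def minimum_calls(n_samples: int, max_missing_frac: float, semantics: str = "tool") -> int:
    """Minimum number of called genotypes a site needs to survive.

    ``tool`` semantics: fraction present >= 1 - max_missing_frac, i.e.
    ceil((1 - f) * n).  ``floor`` semantics: floor((1 - f) * n), the reading
    under which 256 samples at 5% missingness give 243 rather than 244.
    """
    target = (1.0 - max_missing_frac) * n_samples
    if semantics == "tool":
        return int(math.ceil(target - 1e-9))
    if semantics == "floor":
        return int(math.floor(target + 1e-9))
    raise ValidationError("semantics must be 'tool' or 'floor'")


@dataclass
class FilterReport:
    """Per-step removal bookkeeping for the filter cascade."""

    n_input: int
    steps: list[tuple[str, int, int]] = field(default_factory=list)
    min_calls_tool: int | None = None
    min_calls_floor: int | None = None

    @property
    def n_survivors(self) -> int:
        return self.steps[-1][2] if self.steps else self.n_input

    def add(self, name: str, removed: int, remaining: int) -> None:
        self.steps.append((name, removed, remaining))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "removed", "remaining"])


# ---------------------------------------------------------------------------
# VCF I/O


def read_sample_map(path) -> pd.DataFrame:
    """Read the sample->population sidecar TSV.

    Expects columns ``sample_id`` and ``population``; ``generation``,
    ``treatment`` and ``replicate`` are carried through when present.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "population"):
        if col not in df.columns:
            raise ValidationError(f"sample map missing required column {col!r}")
    return df


def read_vcf(path, sample_map_path=None, chromosomes=None):
    """Read a VCF into a :class:`GenotypeMatrix` (ALT dosage orientation).

    Parameters
    ----------
    path
        VCF file (plain or bgzipped).
    sample_map_path
        Optional sample->population TSV; every VCF sample must appear in it.
    chromosomes
        Optional iterable of contig names to keep; records on other contigs
        (unassembled scaffolds) are dropped.

    Returns
    -------
    (GenotypeMatrix, PopulationMap DataFrame or None)
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)

    pop_map = None
    if sample_map_path is not None:
        pop_map = read_sample_map(sample_map_path)
        known = set(pop_map["sample_id"])
        absent = [s for s in samples if s not in known]
        if absent:
            raise ValidationError(
                f"samples present in VCF but absent from sample map: {absent[:5]}"
            )
        pop_map = pop_map.set_index("sample_id").loc[samples].reset_index()

    keep = None if chromosomes is None else set(chromosomes)
    rows, dosages, gqs, dps = [], [], [], []
    for var in vcf:
        if keep is not None and var.CHROM not in keep:
            continue
        geno = var.genotype.array()
        if geno.shape[1] != 3:  # two alleles + phase flag
            raise ValidationError(
                f"non-diploid genotype at {var.CHROM}:{var.POS}"
            )
        alleles = geno[:, :2]
        missing = (alleles < 0).any(axis=1)
        dose = (alleles > 0).sum(axis=1).astype(np.int8)
        dose[missing] = MISSING
        dosages.append(dose)

        def fmt_field(key):
            try:
                arr = var.format(key)
            except KeyError:
                arr = None
            if arr is None:
                return np.full(len(samples), np.nan)
            vals = np.asarray(arr, dtype=float).reshape(len(samples))
            vals[missing] = np.nan
            vals[vals < 0] = np.nan  # negative sentinels mark absent fields
            return vals

        gqs.append(fmt_field("GQ"))
        dps.append(fmt_field("DP"))

        rows.append((var.CHROM, var.POS, var.REF, ",".join(var.ALT)))

    snps = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    n = len(samples)
    dosage = np.vstack(dosages).T if dosages else np.empty((n, 0), dtype=np.int8)
    gq = np.vstack(gqs).T if gqs else None
    dp = np.vstack(dps).T if dps else None
    if gq is not None and np.isnan(gq).all():
        gq = None  # field absent from the VCF
    if dp is not None and np.isnan(dp).all():
        dp = None
    gm = GenotypeMatrix(dosage=dosage, snps=snps, sample_ids=samples, gq=gq, dp=dp)
    return gm, pop_map


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a VCF v4.2 with GT, and GQ/DP when the matrix carries them."""
    has_gq = gm.gq is not None
    has_dp = gm.dp is not None
    fmt_keys = ["GT"] + (["GQ"] if has_gq else []) + (["DP"] if has_dp else [])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=er-driftscan\n")
        chroms = dict.fromkeys(gm.snps["chrom"])
        for c in chroms:
            if contig_lengths and c in contig_lengths:
                fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_gq:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        fmt = ":".join(fmt_keys)
        for j in range(gm.n_snps):
            rec = gm.snps.iloc[j]
            cells = []
            for i in range(gm.n_samples):
                d = int(gm.dosage[i, j])
                parts = [_GT_STRINGS[d]]
                if has_gq:
                    v = gm.gq[i, j]
                    parts.append("." if np.isnan(v) else str(int(round(v))))
                if has_dp:
                    v = gm.dp[i, j]
                    parts.append("." if np.isnan(v) else str(int(round(v))))
                cells.append(":".join(parts))
            fh.write(
                f"{rec.chrom}\t{int(rec.pos)}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Filters


def apply_site_filters(gm: GenotypeMatrix, cfg: FilterConfig):
    """Apply the quality-trimming cascade; returns (filtered, FilterReport).

    Order: chromosome restriction -> missingness -> biallelic -> mean GQ ->
    mean DP -> MAF.  The report records removals per step; the two
    missingness boundary conventions are both reported.
    """
    if gm.n_snps == 0:
        raise ValidationError("cannot filter an empty genotype matrix")

    report = FilterReport(n_input=gm.n_snps)
    report.min_calls_tool = minimum_calls(gm.n_samples, cfg.max_missing_frac, "tool")
    report.min_calls_floor = minimum_calls(gm.n_samples, cfg.max_missing_frac, "floor")

    def step(name: str, keep_mask: np.ndarray, cur: GenotypeMatrix) -> GenotypeMatrix:
        removed = int((~keep_mask).sum())
        out = cur.take_snps(keep_mask) if removed else cur
        report.add(name, removed, out.n_snps)
        return out

    cur = gm
    if cfg.chromosomes is not None:
        keep = cur.snps["chrom"].isin(cfg.chromosomes).to_numpy()
    else:
        keep = np.ones(cur.n_snps, dtype=bool)
    cur = step("chromosomes", keep, cur)

    if cfg.gq_mask_calls and cur.gq is not None:
        low = np.nan_to_num(cur.gq, nan=np.inf) < cfg.min_mean_gq
        if low.any():
            dosage = cur.dosage.copy()
            dosage[low] = MISSING
            gq = cur.gq.copy()
            gq[low] = np.nan
            dp = None if cur.dp is None else cur.dp.copy()
            if dp is not None:
                dp[low] = np.nan
            cur = GenotypeMatrix(
                dosage=dosage, snps=cur.snps, sample_ids=cur.sample_ids, gq=gq, dp=dp
            )

    called = (cur.dosage != MISSING).sum(axis=0)
    min_calls = minimum_calls(cur.n_samples, cfg.max_missing_frac, cfg.missing_semantics)
    cur = step("missingness", called >= min_calls, cur)

    if cfg.biallelic_only:
        n_alt = cur.snps["alt"].str.count(",").to_numpy() + 1
        keep = n_alt == 1
    else:
        keep = np.ones(cur.n_snps, dtype=bool)
    cur = step("biallelic", keep, cur)

    if cur.gq is not None and not cfg.gq_mask_calls:
        with np.errstate(invalid="ignore"):
            mean_gq = np.nanmean(cur.gq, axis=0)
            mean_gq = np.nan_to_num(mean_gq, nan=-np.inf)
        keep = mean_gq >= cfg.min_mean_gq
    else:
        keep = np.ones(cur.n_snps, dtype=bool)
    cur = step("mean_gq", keep, cur)

    if cur.dp is not None:
        with np.errstate(invalid="ignore"):
            mean_dp = np.nanmean(cur.dp, axis=0)
        keep = mean_dp > cfg.max_mean_dp if cfg.invert_mean_dp else mean_dp <= cfg.max_mean_dp
    else:
        keep = np.ones(cur.n_snps, dtype=bool)
    cur = step("mean_dp", keep, cur)

    af_alt = pooled_alt_frequency(cur)
    with np.errstate(invalid="ignore"):
        maf = np.fmin(af_alt, 1.0 - af_alt)
    keep = maf >= cfg.min_maf
    keep &= ~np.isnan(maf)
    cur = step("maf", keep, cur)

    return cur, report


# ---------------------------------------------------------------------------
# Allele frequencies and marker density


def pooled_alt_frequency(gm: GenotypeMatrix) -> np.ndarray:
    """ALT-allele frequency per SNP pooled over all samples (nan if uncalled)."""
    called = gm.dosage != MISSING
    n_called = called.sum(axis=0)
    alt_sum = np.where(called, gm.dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(n_called > 0, alt_sum / (2.0 * n_called), np.nan)
    return af


def allele_frequencies(gm: GenotypeMatrix, pop_map: pd.DataFrame) -> pd.DataFrame:
    """Reference-allele frequency per SNP per population.

    AF_ref = (2*n_homREF + n_het) / (2*n_called) over non-missing calls.
    SNPs with no called sample in a population get ``nan`` (not 0).

    Returns a long DataFrame: chrom, pos, population, af_ref, n_called.
    """
    pops = pop_map.groupby("population", sort=False)["sample_id"].apply(list)
    if (pops.str.len() == 0).any():
        raise ValidationError("every population needs at least one sample")
    frames = []
    for pop, sample_ids in pops.items():
        sub = gm.take_samples(sample_ids)
        called = sub.dosage != MISSING
        n_called = called.sum(axis=0)
        alt_sum = np.where(called, sub.dosage, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            af_alt = np.where(n_called > 0, alt_sum / (2.0 * n_called), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": gm.snps["chrom"],
                    "pos": gm.snps["pos"],
                    "population": pop,
                    "af_ref": 1.0 - af_alt,
                    "n_called": n_called,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def marker_density(gm: GenotypeMatrix, chrom_lengths: dict[str, int]):
    """SNPs per Mb per chromosome and the mean across chromosomes.

    Returns (Series indexed by chromosome, mean_density).
    """
    counts = gm.snps["chrom"].value_counts()
    for c in counts.index:
        if c not in chrom_lengths:
            raise ValidationError(f"chromosome {c!r} has no declared length")
    if any(l <= 0 for l in chrom_lengths.values()):
        raise ValidationError("chromosome lengths must be positive")
    dens = pd.Series(
        {c: counts.get(c, 0) / (l / 1e6) for c, l in chrom_lengths.items()},
        name="snps_per_mb",
    )
    return dens, float(dens.mean())
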