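"""Population differentiation and diversity statistics.

Per-group allele counts, the fixed interspecific SNP rule, windowed
Weir & Cockerham (1984) and Hudson FST, nucleotide diversity, and
dosage-correlation linkage disequilibrium (r2) with a decay curve.

Estimator conventions
---------------------
* Weir & Cockerham: per-site variance components a (among populations),
  b (among individuals within populations) and c (within individuals);
  the window/genome estimate is the "weighted" ratio sum(a)/sum(a+b+c).
* Hudson: ratio of sums of the per-site unbiased numerator
  ``(p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)`` (allele-count n)
  over the between-population heterozygosity ``p1(1-p2) + p2(1-p1)``.
* Sites where either group has fewer than 2 called genotypes, or a group
  call rate below ``min_call_rate``, are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import GenotypeMatrix, Window


@dataclass
class AlleleCounts:
    """Per-site alt-allele copies and called allele copies for one group."""

    group: str
    alt: np.ndarray  # alt allele copies among called genotypes
    called: np.ndarray  # 2 * number of called genotypes
    n_samples: int

    def freq(self) -> np.ndarray:
        """Alt-allele frequency; NaN where no genotype is called."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.called > 0, self.alt / self.called, np.nan)


def allele_counts(
    gm: GenotypeMatrix, group: str, sites: np.ndarray | None = None
) -> AlleleCounts:
    """Alt and called allele copies per site for one group.

    ``alt = sum of dosages over non-missing calls``;
    ``called = 2 x number of non-missing calls``.
    """
    idx = gm.group_indices(group)
    calls = gm.calls[idx, :]
    if sites is not None:
        calls = calls[:, np.asarray(sites)]
    called_geno = (calls >= 0).sum(axis=0)
    alt = np.where(calls >= 0, calls, 0).sum(axis=0)
    return AlleleCounts(
        group=group,
        alt=alt.astype(np.int64),
        called=(2 * called_geno).astype(np.int64),
        n_samples=idx.size,
    )


@dataclass
class FixedSiteSet:
    """Sites flagged as fixed interspecific differences.

    ``orientation`` is +1 where group A is (near-)fixed reference and
    group B (near-)fixed alternate, -1 for the mirrored polarity.
    """

    flagged: np.ndarray  # boolean per site
    orientation: np.ndarray  # int8 per site: 0 not flagged, +1 / -1
    max_frac_a: float
    min_frac_b: float

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.flagged)

    @property
    def n_fixed(self) -> int:
        return int(self.flagged.sum())


#: Fractional thresholds implied by absolute counts of <6/318 and >134/140
#: alt alleles on the original 159+70 accession panels.
FIXED_MAX_FRAC_A = 6 / 318
FIXED_MIN_FRAC_B = 134 / 140


def identify_fixed_snps(
    counts_a: AlleleCounts,
    counts_b: AlleleCounts,
    max_alt_a: int | None = None,
    min_alt_b: int | None = None,
) -> FixedSiteSet:
    """Flag sites where the two species carry (near-)alternative alleles.

    With absolute thresholds, a site is flagged when
    ``alt_A < max_alt_a and alt_B > min_alt_b`` (or the mirrored
    orientation).  Without them the equivalent fractional rule
    ``alt_A/called_A < 6/318`` and ``alt_B/called_B > 134/140`` is applied,
    which scales to any panel size.  Ref/alt polarity is arbitrary, so the
    mirrored orientation (A near-fixed alt, B near-fixed ref) is always
    evaluated too.
    """
    if counts_a.alt.shape != counts_b.alt.shape:
        raise ValueError("allele-count site lists differ in length")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_a = np.where(counts_a.called > 0, counts_a.alt / counts_a.called, np.nan)
        frac_b = np.where(counts_b.called > 0, counts_b.alt / counts_b.called, np.nan)
    if max_alt_a is not None and min_alt_b is not None:
        lo_a = counts_a.alt < max_alt_a
        hi_b = counts_b.alt > min_alt_b
        hi_a = counts_a.alt > (counts_a.called - max_alt_a)
        lo_b = counts_b.alt < (counts_b.called - min_alt_b)
        max_frac_a = float(max_alt_a) / max(2 * counts_a.n_samples, 1)
        min_frac_b = float(min_alt_b) / max(2 * counts_b.n_samples, 1)
    elif max_alt_a is None and min_alt_b is None:
        with np.errstate(invalid="ignore"):
            lo_a = frac_a < FIXED_MAX_FRAC_A
            hi_b = frac_b > FIXED_MIN_FRAC_B
            hi_a = frac_a > 1 - FIXED_MAX_FRAC_A
            lo_b = frac_b < 1 - FIXED_MIN_FRAC_B
        max_frac_a, min_frac_b = FIXED_MAX_FRAC_A, FIXED_MIN_FRAC_B
    else:
        raise ValueError("pass both absolute thresholds or neither")
    called = (counts_a.called > 0) & (counts_b.called > 0)
    fwd = lo_a & hi_b & called
    rev = hi_a & lo_b & called
    orientation = np.zeros(counts_a.alt.shape, dtype=np.int8)
    orientation[fwd] = 1
    orientation[rev & ~fwd] = -1
    return FixedSiteSet(
        flagged=fwd | rev,
        orientation=orientation,
        max_frac_a=max_frac_a,
        min_frac_b=min_frac_b,
    )


# -- FST ----------------------------------------------------------------------

def _group_site_stats(gm: GenotypeMatrix, group: str):
    """Per-site (n called diploids, alt freq, observed het freq) for a group."""
    calls = gm.calls[gm.group_indices(group), :]
    called = calls >= 0
    n = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, calls, 0).sum(axis=0) / np.maximum(2 * n, 1)
        h = (calls == 1).sum(axis=0) / np.maximum(n, 1)
    return n, p, h


def wc_site_components(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) per-site a, b, c for two populations.

    Inputs are per-site called diploid counts, alt frequencies and
    observed heterozygote frequencies.  Returns (a, b, c, usable) where
    ``usable`` marks sites with >= 2 called genotypes in both groups.
    """
    n1 = n1.astype(float)
    n2 = n2.astype(float)
    usable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / 2.0
        nc = 2.0 * nbar - (n1**2 + n2**2) / (2.0 * nbar)
        pbar = (n1 * p1 + n2 * p2) / (2.0 * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / (2.0 * nbar)
        inner = pbar * (1 - pbar) - s2 / 2.0
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    for arr in (a, b, c):
        arr[~usable] = 0.0
    return a, b, c, usable


def hudson_site_components(
    c1: np.ndarray, p1: np.ndarray, c2: np.ndarray, p2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hudson per-site numerator/denominator; c1, c2 are allele counts.

    Plug-in form: numerator ``(p1 - p2)^2``, denominator
    ``p1(1-p2) + p2(1-p1)`` (between-population heterozygosity), so two
    panels with identical calls give exactly 0 and a fixed difference
    gives exactly 1.  Aggregation is ratio of sums.
    """
    c1 = c1.astype(float)
    c2 = c2.astype(float)
    usable = (c1 >= 4) & (c2 >= 4)  # >= 2 diploid genotypes each
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (p1 - p2) ** 2
        den = p1 * (1 - p2) + p2 * (1 - p1)
    num[~usable] = 0.0
    den[~usable] = 0.0
    return num, den, usable


@dataclass
class FstEstimate:
    window: Window
    fst: float  # Weir-Cockerham weighted
    fst_hudson: float
    n_snps: int


def _usable_site_mask(
    gm: GenotypeMatrix, group1: str, group2: str, min_call_rate: float
):
    n1, p1, h1 = _group_site_stats(gm, group1)
    n2, p2, h2 = _group_site_stats(gm, group2)
    s1 = gm.group_indices(group1).size
    s2 = gm.group_indices(group2).size
    ok = (n1 >= 2) & (n2 >= 2)
    ok &= (n1 >= min_call_rate * s1) & (n2 >= min_call_rate * s2)
    return (n1, p1, h1, n2, p2, h2), ok


def fst_components(
    gm: GenotypeMatrix, group1: str, group2: str, min_call_rate: float = 0.5
):
    """Per-site WC (a, b, c) and Hudson (num, den) arrays plus a usable mask."""
    if group1 == group2:
        raise ValueError("groups must differ")
    if set(gm.group_ids(group1)) & set(gm.group_ids(group2)):
        raise ValueError("groups overlap")
    (n1, p1, h1, n2, p2, h2), ok = _usable_site_mask(
        gm, group1, group2, min_call_rate
    )
    a, b, c, _ = wc_site_components(n1, p1, h1, n2, p2, h2)
    hn, hd, _ = hudson_site_components(2 * n1, p1, 2 * n2, p2)
    for arr in (a, b, c, hn, hd):
        arr[~ok] = 0.0
    return a, b, c, hn, hd, ok


def _ratio(num: float, den: float) -> float:
    return float(num / den) if den != 0.0 else float("nan")


def fst_wc_windowed(
    gm: GenotypeMatrix,
    group1: str,
    group2: str,
    windows: list[Window],
    min_call_rate: float = 0.5,
) -> list[FstEstimate]:
    """Windowed weighted Weir-Cockerham and Hudson FST.

    Windows containing no usable SNP are omitted.
    """
    a, b, c, hn, hd, ok = fst_components(gm, group1, group2, min_call_rate)
    abc = a + b + c
    out: list[FstEstimate] = []
    for w in windows:
        m = gm.site_mask(w) & ok
        n_snps = int(m.sum())
        if n_snps == 0:
            continue
        out.append(
            FstEstimate(
                window=w,
                fst=_ratio(a[m].sum(), abc[m].sum()),
                fst_hudson=_ratio(hn[m].sum(), hd[m].sum()),
                n_snps=n_snps,
            )
        )
    return out


@dataclass
class GenomewideFst:
    fst_wc: float
    fst_wc_mean: float  # mean of per-site ratios (vcftools "mean FST")
    fst_hudson: float
    n_snps: int


def fst_genomewide(
    gm: GenotypeMatrix,
    group1: str,
    group2: str,
    site_mask: np.ndarray | None = None,
    min_call_rate: float = 0.5,
) -> GenomewideFst:
    a, b, c, hn, hd, ok = fst_components(gm, group1, group2, min_call_rate)
    m = ok if site_mask is None else (ok & site_mask)
    abc = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = np.where(abc > 0, a / np.where(abc > 0, abc, 1.0), np.nan)
    per_site_ok = per_site[m & np.isfinite(per_site)]
    return GenomewideFst(
        fst_wc=_ratio(a[m].sum(), abc[m].sum()),
        fst_wc_mean=float(per_site_ok.mean()) if per_site_ok.size else float("nan"),
        fst_hudson=_ratio(hn[m].sum(), hd[m].sum()),
        n_snps=int(m.sum()),
    )


def fst_masked(
    gm: GenotypeMatrix,
    group1: str,
    group2: str,
    mask_intervals: pd.DataFrame,
    min_call_rate: float = 0.5,
) -> dict:
    """Genome-wide weighted FST with all sites vs. excluding masked intervals.

    ``mask_intervals`` is an interval frame (chrom, start, end, ...); the
    "without" estimate uses only sites outside every interval.  Raises if
    the mask covers every usable site.
    """
    inside = np.zeros(gm.n_sites, dtype=bool)
    for row in mask_intervals.itertuples():
        inside |= gm.site_mask(Window(str(row.chrom), int(row.start), int(row.end)))
    with_all = fst_genomewide(gm, group1, group2, None, min_call_rate)
    if not (~inside).any():
        raise ValueError("mask covers all sites; nothing left to estimate")
    without = fst_genomewide(gm, group1, group2, ~inside, min_call_rate)
    if without.n_snps == 0:
        raise ValueError("mask covers all usable sites")
    return {
        "fst_with": with_all.fst_wc,
        "fst_without": without.fst_wc,
        "fst_hudson_with": with_all.fst_hudson,
        "fst_hudson_without": without.fst_hudson,
        "n_snps_with": with_all.n_snps,
        "n_snps_without": without.n_snps,
    }


# -- diversity ----------------------------------------------------------------

@dataclass
class DiversityEstimate:
    window: Window
    pi: float  # per-bp nucleotide diversity (sum of per-site pi / window bp)
    n_variants: int
    density: float  # variants per kb


def site_pi(counts: AlleleCounts) -> np.ndarray:
    """Unbiased per-site diversity ``2*alt*(called-alt) / (called*(called-1))``."""
    alt = counts.alt.astype(float)
    called = counts.called.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * alt * (called - alt) / (called * (called - 1.0))
    pi[called < 2] = 0.0
    return pi


def diversity_windowed(
    gm: GenotypeMatrix, group: str, windows: list[Window]
) -> list[DiversityEstimate]:
    """Windowed per-bp nucleotide diversity and SNP density for one group."""
    if not windows:
        raise ValueError("empty window list")
    counts = allele_counts(gm, group)
    pi = site_pi(counts)
    out: list[DiversityEstimate] = []
    for w in windows:
        m = gm.site_mask(w)
        n = int(m.sum())
        out.append(
            DiversityEstimate(
                window=w,
                pi=float(pi[m].sum()) / w.length,
                n_variants=n,
                density=n / (w.length / 1000.0),
            )
        )
    return out


# -- linkage disequilibrium ---------------------------------------------------

def ld_r2(
    gm: GenotypeMatrix, group: str, site_pairs: list[tuple[int, int]]
) -> list[float]:
    """Squared Pearson correlation of dosages over shared non-missing samples.

    Monomorphic pairs (fewer than two distinct dosages at either site among
    the shared samples) yield NaN, not 0.
    """
    calls = gm.calls[gm.group_indices(group), :]
    out: list[float] = []
    for i, j in site_pairs:
        x = calls[:, i].astype(float)
        y = calls[:, j].astype(float)
        shared = (x >= 0) & (y >= 0)
        x, y = x[shared], y[shared]
        if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
            out.append(float("nan"))
            continue
        r = np.corrcoef(x, y)[0, 1]
        out.append(float(r * r))
    return out


def ld_decay(
    gm: GenotypeMatrix,
    group: str,
    max_dist: int = 500_000,
    bin_size: int = 10_000,
    max_pairs_per_site: int = 25,
) -> tuple[pd.DataFrame, float]:
    """Distance-binned mean r2 and the LD-decay distance.

    Pairs are formed within chromosomes up to ``max_dist`` apart (capped
    per site to bound work).  The decay distance is the midpoint of the
    first bin whose mean r2 drops below half the maximum bin mean; it is
    the default radius for merging nearby introgression loci into events.
    Returns ``(table, decay_distance_bp)``; the distance is NaN when no
    bin falls below half-maximum.
    """
    idx = gm.group_indices(group)
    calls = gm.calls[idx, :]
    dists: list[int] = []
    r2s: list[float] = []
    for chrom in gm.chromosomes():
        sites = np.flatnonzero(gm.chrom == chrom)
        pos = gm.pos[sites]
        for a_i, i in enumerate(sites):
            upper = np.searchsorted(pos, pos[a_i] + max_dist, side="right")
            partners = sites[a_i + 1 : upper][:max_pairs_per_site]
            for j in partners:
                x = calls[:, i].astype(float)
                y = calls[:, j].astype(float)
                shared = (x >= 0) & (y >= 0)
                x, y = x[shared], y[shared]
                if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
                    continue
                r = np.corrcoef(x, y)[0, 1]
                dists.append(int(gm.pos[j] - gm.pos[i]))
                r2s.append(float(r * r))
    if not r2s:
        return pd.DataFrame(columns=["dist_bin", "mean_r2", "n_pairs"]), float("nan")
    df = pd.DataFrame({"dist": dists, "r2": r2s})
    df["dist_bin"] = (df["dist"] // bin_size) * bin_size + bin_size // 2
    table = (
        df.groupby("dist_bin")["r2"]
        .agg(mean_r2="mean", n_pairs="size")
        .reset_index()
        .sort_values("dist_bin", ignore_index=True)
    )
    half_max = table["mean_r2"].max() / 2.0
    below = table.index[table["mean_r2"] < half_max]
    decay = float(table.loc[below[0], "dist_bin"]) if len(below) else float("nan")
    return table, decay
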