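"""Sampling windows, genotype-matrix encoding, widths, VCF ingestion, stats.

The estimator's two inputs are produced here: an ``m x c`` minor-allele
genotype matrix (``c = n`` unphased columns or ``2n`` phased columns, zero
padded on the right to ``pad_to``) and the sampling width — the largest
pairwise distance among the sampled individuals (Euclidean in habitat units
for simulated data, WGS84 geodesic kilometres for lat/lon data).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ancestry import SiteSet
from .geodesic import geodesic_km
from .simulate import PopulationState

__all__ = [
    "SampleSpec",
    "GenotypeMatrix",
    "SummaryStatVector",
    "MonomorphicSiteError",
    "place_sampling_window",
    "sample_individuals",
    "segregating_site_indices",
    "encode_genotypes",
    "sampling_width",
    "read_vcf_filtered",
    "write_vcf",
    "summary_stats",
]

STRATEGIES = ("uniform", "point", "cluster", "half-biased", "transect")


@dataclass
class SampleSpec:
    """How to place a sampling window and draw individuals from it."""

    n: int
    width_fraction: float = 1.0
    edge_crop: float = 0.0
    strategy: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.width_fraction <= 1:
            raise ValueError("width_fraction must be in (0, 1]")
        if self.n < 2:
            raise ValueError("need n >= 2")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")


@dataclass
class GenotypeMatrix:
    """Minor-allele-encoded ``m x pad_to`` matrix.

    Unphased entries are 0/1/2 minor-allele counts, one column per
    individual; phased entries are 0/1 with two randomly ordered columns
    per individual.  Columns beyond the sample are zero padding.
    """

    values: np.ndarray
    phased: bool
    n_individuals: int
    pad_to: int

    def __post_init__(self) -> None:
        if self.values.shape[1] != self.pad_to:
            raise ValueError("matrix width must equal pad_to")
        if self.num_columns > self.pad_to:
            raise ValueError("pad_to smaller than the data columns")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def num_columns(self) -> int:
        """Data (non-padding) columns."""
        return (2 if self.phased else 1) * self.n_individuals

    @property
    def unpadded(self) -> np.ndarray:
        return self.values[:, : self.num_columns]

    def genotype_counts(self) -> np.ndarray:
        """Per-individual minor-allele counts (m x n), phased or not."""
        g = self.unpadded
        if self.phased:
            return g[:, 0::2] + g[:, 1::2]
        return g


@dataclass
class SummaryStatVector:
    """Per-site-averaged summary statistics of a genotype matrix."""

    pi: float
    tajima_d: float
    f_is: float
    h_obs: float
    h_exp: float

    def as_array(self) -> np.ndarray:
        return np.array([self.pi, self.tajima_d, self.f_is, self.h_obs, self.h_exp])


class MonomorphicSiteError(ValueError):
    """A site is monomorphic in the chosen sample; caller should resample."""

    def __init__(self, site_indices):
        self.site_indices = list(site_indices)
        super().__init__(f"monomorphic sites in sample: {self.site_indices[:10]}"
                         f"{'...' if len(self.site_indices) > 10 else ''}")


# -- window and individual sampling ---------------------------------------

def place_sampling_window(W: float, spec: SampleSpec,
                          rng: np.random.Generator) -> tuple[float, float, float]:
    """Uniform-random square window inside the edge-cropped habitat.

    Returns ``(x0, y0, side)`` with ``side = width_fraction * W``, clamped
    so the window sits wholly inside ``[edge_crop, W - edge_crop]^2``
    (a full-width window on a cropped habitat is the cropped square).
    """
    lo, hi = spec.edge_crop, W - spec.edge_crop
    side = min(spec.width_fraction * W, hi - lo)
    slack = (hi - lo) - side
    if hi - lo <= 0 or side <= 0:
        raise ValueError("sampling window cannot fit inside the cropped habitat")
    slack = max(slack, 0.0)
    x0 = lo + rng.uniform(0.0, 1.0) * slack
    y0 = lo + rng.uniform(0.0, 1.0) * slack
    return (float(x0), float(y0), float(side))


def sample_individuals(pop: PopulationState, window: tuple[float, float, float],
                       spec: SampleSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw ``spec.n`` distinct living individuals from the window.

    ``uniform`` draws with equal probability.  The alternative geometries
    are conventions (see docs): ``point`` takes the n individuals nearest a
    uniform-random point; ``cluster`` draws around 4 Gaussian cluster
    centres of SD ``side/20``; ``half-biased`` takes 80% of draws from the
    left half; ``transect`` samples uniformly within a horizontal band of
    height ``side/10`` across the window centre.
    """
    x0, y0, side = window
    idx = pop.alive_indices
    px, py = pop.x[idx], pop.y[idx]
    inside = (px >= x0) & (px <= x0 + side) & (py >= y0) & (py <= y0 + side)
    idx, px, py = idx[inside], px[inside], py[inside]
    n = spec.n

    def _fail(reason: str):
        raise ValueError(f"cannot draw n={n} individuals with strategy "
                         f"'{spec.strategy}': {reason}")

    if spec.strategy == "uniform":
        if idx.size < n:
            _fail(f"only {idx.size} individuals in window")
        return rng.choice(idx, size=n, replace=False)
    if spec.strategy == "point":
        if idx.size < n:
            _fail(f"only {idx.size} individuals in window")
        cx, cy = rng.uniform(x0, x0 + side), rng.uniform(y0, y0 + side)
        order = np.argsort((px - cx) ** 2 + (py - cy) ** 2, kind="stable")
        return idx[order[:n]]
    if spec.strategy == "cluster":
        if idx.size < n:
            _fail(f"only {idx.size} individuals in window")
        centres = np.column_stack([rng.uniform(x0, x0 + side, 4),
                                   rng.uniform(y0, y0 + side, 4)])
        chosen: list[int] = []
        free = np.ones(idx.size, dtype=bool)
        for _ in range(n):
            c = centres[rng.integers(4)]
            tx, ty = rng.normal(c, side / 20.0)
            cand = np.flatnonzero(free)
            k = cand[np.argmin((px[cand] - tx) ** 2 + (py[cand] - ty) ** 2)]
            chosen.append(idx[k])
            free[k] = False
        return np.asarray(chosen)
    if spec.strategy == "half-biased":
        left = px <= x0 + side / 2.0
        n_left = int(round(0.8 * n))
        n_right = n - n_left
        if left.sum() < n_left or (~left).sum() < n_right:
            _fail("a half of the window has too few individuals")
        a = rng.choice(idx[left], size=n_left, replace=False)
        b = rng.choice(idx[~left], size=n_right, replace=False)
        return np.concatenate([a, b])
    # transect
    band = np.abs(py - (y0 + side / 2.0)) <= side / 20.0
    if band.sum() < n:
        _fail("transect band has too few individuals")
    return rng.choice(idx[band], size=n, replace=False)


# -- genotype encoding -----------------------------------------------------

def segregating_site_indices(sites: SiteSet, sample_rows: Sequence[int]) -> np.ndarray:
    """Indices of sites polymorphic among the given sampled individuals."""
    cols = _haplotype_columns(sites, sample_rows)
    h = sites.haplotypes[:, cols]
    freq = h.mean(axis=1)
    return np.flatnonzero((freq > 0) & (freq < 1))


def _haplotype_columns(sites: SiteSet, sample_rows: Sequence[int]) -> np.ndarray:
    pos = {int(r): j for j, r in enumerate(sites.sample_rows)}
    cols = []
    for r in sample_rows:
        try:
            j = pos[int(r)]
        except KeyError:
            raise KeyError(f"individual row {r} not among the genotyped samples")
        cols.extend((2 * j, 2 * j + 1))
    return np.asarray(cols)


def encode_genotypes(sample_rows: Sequence[int], sites: SiteSet, phased: bool,
                     pad_to: Optional[int], rng: np.random.Generator) -> GenotypeMatrix:
    """Minor-allele encode the given individuals at the given sites.

    The minor allele at each site is the one at sample frequency < 0.5
    (ties break to the lexicographically smaller allele string, i.e. the
    allele coded 0 by the ancestry stage).  Phased output keeps two columns
    per individual in randomised within-individual order; unphased output
    holds minor-allele counts.  Monomorphic sites raise
    :class:`MonomorphicSiteError` so the caller can resample sites.
    """
    cols = _haplotype_columns(sites, sample_rows)
    h = sites.haplotypes[:, cols].astype(np.int16)
    freq1 = h.mean(axis=1)
    mono = (freq1 == 0) | (freq1 == 1)
    if mono.any():
        raise MonomorphicSiteError(np.flatnonzero(mono))
    # allele 1 is the lexicographically larger string; at a tie the smaller
    # string (allele 0) is the designated minor allele
    flip = freq1 >= 0.5
    h = np.where(flip[:, None], 1 - h, h)
    n = len(sample_rows)
    if phased:
        swap = rng.integers(0, 2, size=n).astype(bool)
        data = h.copy()
        for j in np.flatnonzero(swap):
            data[:, [2 * j, 2 * j + 1]] = data[:, [2 * j + 1, 2 * j]]
    else:
        data = h[:, 0::2] + h[:, 1::2]
    width = data.shape[1]
    pad_to = width if pad_to is None else int(pad_to)
    if pad_to < width:
        raise ValueError("pad_to smaller than the data columns")
    out = np.zeros((data.shape[0], pad_to), dtype=np.int16)
    out[:, :width] = data
    return GenotypeMatrix(values=out, phased=phased, n_individuals=n, pad_to=pad_to)


def sampling_width(locations: np.ndarray, metric: str = "euclidean") -> float:
    """Largest pairwise distance among locations.

    ``euclidean`` expects (x, y) in habitat units; ``geodesic`` expects
    (lat, lon) degrees and returns WGS84 kilometres.
    """
    loc = np.asarray(locations, dtype=float)
    if loc.ndim != 2 or loc.shape[0] < 2:
        raise ValueError("need at least two locations")
    if np.unique(loc, axis=0).shape[0] < 2:
        raise ValueError("need at least two distinct locations")
    if metric == "euclidean":
        d2 = ((loc[:, None, :] - loc[None, :, :]) ** 2).sum(-1)
        return float(np.sqrt(d2.max()))
    if metric == "geodesic":
        best = 0.0
        for i in range(loc.shape[0]):
            for j in range(i + 1, loc.shape[0]):
                best = max(best, geodesic_km(loc[i, 0], loc[i, 1], loc[j, 0], loc[j, 1]))
        return best
    raise ValueError("metric must be 'euclidean' or 'geodesic'")


# -- VCF ingestion / export ------------------------------------------------

def read_vcf_filtered(path: str, locations_table: pd.DataFrame | str,
                      missing_fraction_allowed: float = 0.0,
                      seed: int = 0) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Load a VCF plus a locations table into a genotype matrix.

    Filtering follows the empirical-data rules: indels and sites with one
    or more than two observed alleles are removed; one random individual is
    kept per duplicated location; a site is retained only when its
    genotyped fraction is at least ``1 - missing_fraction_allowed``;
    remaining missing genotypes are imputed with the major allele; sites
    monomorphic in the retained individuals are dropped; entries are
    minor-allele counts (unphased).

    ``locations_table`` has columns (id, x, y) or (id, lat, lon); any
    mismatch between VCF sample ids and table ids raises with the
    offending ids listed.
    """
    from cyvcf2 import VCF

    if isinstance(locations_table, (str, bytes)):
        locations_table = pd.read_csv(locations_table, sep=None, engine="python",
                                      header=None, comment="#")
    loc = locations_table.copy()
    loc.columns = ["id", "x", "y"] + list(loc.columns[3:])
    loc["id"] = loc["id"].astype(str)

    vcf = VCF(str(path), gts012=True)
    vcf_ids = [str(s) for s in vcf.samples]
    missing_in_table = sorted(set(vcf_ids) - set(loc["id"]))
    missing_in_vcf = sorted(set(loc["id"]) - set(vcf_ids))
    if missing_in_table or missing_in_vcf:
        raise ValueError(
            "sample-id mismatch between VCF and locations table; "
            f"missing locations for {missing_in_table}; "
            f"not in VCF: {missing_in_vcf}")

    # one random individual per duplicated location (seeded)
    rng = np.random.default_rng(seed)
    loc = loc.set_index("id").loc[vcf_ids].reset_index()
    keep_ids: list[str] = []
    for _, group in loc.groupby(["x", "y"], sort=True):
        ids = sorted(group["id"].tolist())
        keep_ids.append(ids[rng.integers(len(ids))] if len(ids) > 1 else ids[0])
    keep_mask = np.array([sid in set(keep_ids) for sid in vcf_ids])
    kept_cols = np.flatnonzero(keep_mask)
    n = kept_cols.size

    rows = []
    for var in vcf:
        if var.is_indel or not var.is_snp or len(var.ALT) != 1:
            continue
        # gts012: 0/1/2 = alt count, 3 = missing
        g = np.asarray(var.gt_types)[kept_cols].astype(np.int16)
        known = g != 3
        if known.mean() < 1.0 - missing_fraction_allowed - 1e-12:
            continue
        if known.sum() == 0:
            continue
        alt_count = g[known].sum()
        major_geno = 2 if alt_count > known.sum() else 0  # per-individual fill
        g[~known] = major_geno
        total = int(g.sum())
        if total == 0 or total == 2 * n:
            continue  # monomorphic in the sampled subset
        # orient to the minor allele; a 50% tie designates the
        # lexicographically smaller allele string as minor
        if total > n or (total == n and str(var.REF) < str(var.ALT[0])):
            g = 2 - g
        rows.append(g)
    vcf.close()
    values = np.asarray(rows, dtype=np.int16) if rows else np.empty((0, n), np.int16)
    gm = GenotypeMatrix(values=values, phased=False, n_individuals=n, pad_to=n)
    kept_loc = loc[loc["id"].isin(keep_ids)].reset_index(drop=True)
    return gm, kept_loc


def write_vcf(sites: SiteSet, sample_names: Sequence[str], path: str,
              phased: bool = True, contig: str = "1") -> None:
    """Export a site set as a minimal diploid VCF (v4.2)."""
    h = sites.haplotypes
    n = len(sites.sample_rows)
    if len(sample_names) != n:
        raise ValueError("one sample name per sampled individual required")
    sep = "|" if phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, sample_names)) + "\n")
        order = np.argsort(sites.positions, kind="stable")
        for i in order:
            gts = [f"{h[i, 2 * j]}{sep}{h[i, 2 * j + 1]}" for j in range(n)]
            fh.write(f"{contig}\t{int(sites.positions[i]) + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


# -- summary statistics ----------------------------------------------------

def summary_stats(gm: GenotypeMatrix) -> SummaryStatVector:
    """Nucleotide diversity, Tajima's D, F_IS, observed/expected heterozygosity.

    All statistics are computed over the ``m`` SNPs of the matrix (averaged
    per site where applicable) using the standard sample-size-corrected
    estimators.  An all-monomorphic matrix yields ``pi = 0`` and D and
    F_IS reported as NaN.
    """
    geno = gm.genotype_counts().astype(float)
    m, n = geno.shape
    if n < 2:
        raise ValueError("need at least two individuals")
    nh = 2 * n  # haplotypes
    c = geno.sum(axis=1)  # minor-allele count per site
    seg = (c > 0) & (c < nh)
    S = int(seg.sum())
    pi_site = 2.0 * c * (nh - c) / (nh * (nh - 1))
    pi = float(pi_site.mean())
    h_obs = float((geno == 1).mean())
    p = c / nh
    h_exp = float((2.0 * p * (1.0 - p) * nh / (nh - 1)).mean())
    f_is = 1.0 - h_obs / h_exp if h_exp > 0 else float("nan")
    if S == 0:
        return SummaryStatVector(pi=0.0, tajima_d=float("nan"), f_is=f_is,
                                 h_obs=h_obs, h_exp=h_exp)
    d = _tajimas_d(nh, S, float(pi_site.sum()))
    return SummaryStatVector(pi=pi, tajima_d=d, f_is=f_is, h_obs=h_obs, h_exp=h_exp)


def _tajimas_d(n_hap: int, S: int, pi_total: float) -> float:
    i = np.arange(1, n_hap)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n_hap + 1.0) / (3.0 * (n_hap - 1.0))
    b2 = 2.0 * (n_hap**2 + n_hap + 3.0) / (9.0 * n_hap * (n_hap - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n_hap + 2.0) / (a1 * n_hap) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    if var <= 0:
        return float("nan")
    return float((pi_total - S / a1) / np.sqrt(var))
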