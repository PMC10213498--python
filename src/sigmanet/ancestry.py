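"""Genetic ancestry: pedigree-constrained inheritance, recapitation, mutations.

The forward simulator records a pedigree but no genomes.  Genetic data for a
set of sampled individuals are produced in three stages:

1. The sampled individuals' ancestor closure is extracted from the pedigree
   and handed to ``msprime`` as a fixed pedigree: meiosis (fair choice of
   starting haplotype, Poisson crossovers at the model recombination rate)
   is simulated through the recorded spatial-epoch genealogy.
2. Lineages still uncoalesced at the epoch boundary are completed by a
   panmictic coalescent ("recapitation") whose present-day size equals the
   census population size, optionally with one instantaneous size change
   (two-epoch demography).
3. Neutral mutations are overlaid, starting from rate 1e-15 per bp per
   generation and escalating tenfold until at least ``m`` biallelic sites
   segregate in the sample; a uniform subsample of exactly ``m`` sites is
   returned.  By the Poisson thinning property this is equivalent in
   distribution to simulating at a high rate and subsampling ``m`` variable
   sites, so the output does not depend on the mutation rate.

Two linkage modes are supported, both on the model genome (defaults: 1e8 bp
at 1e-8 crossovers/bp, i.e. one Morgan).  ``unlinked`` (RADseq-like, the
default) additionally enforces a minimum spacing of ``genome_length/(2m)``
between the subsampled SNPs so they are spread across the genome and are
mostly independent; ``linked`` subsamples uniformly without a spacing
constraint, so nearby (linked) SNPs can co-occur as in whole-genome data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import msprime
import numpy as np
import tskit

from .rng import derive_seed
from .simulate import PopulationState

__all__ = [
    "DemographicHistory",
    "AncestryRecord",
    "SiteSet",
    "build_pedigree_tables",
    "init_ancestral_diversity",
    "overlay_mutations_until_m",
    "sample_crossovers",
    "inherit_recombinant_haplotype",
]



@dataclass
class DemographicHistory:
    """Ancestral-size history for the panmictic (recapitation) phase.

    ``mode="constant"`` keeps the ancestral size at the present-day census.
    ``mode="step"`` applies one instantaneous change ``change_time``
    generations before sampling, to ``N_anc_multiplier`` times the
    present-day size.
    """

    N_anc_multiplier: float = 1.0
    change_time: float = 1000.0
    mode: str = "constant"

    def __post_init__(self) -> None:
        if not self.N_anc_multiplier > 0:
            raise ValueError("N_anc_multiplier must be > 0")
        if not self.change_time >= 1:
            raise ValueError("change_time must be >= 1")
        if self.mode not in ("constant", "step"):
            raise ValueError("mode must be 'constant' or 'step'")


@dataclass
class AncestryRecord:
    """Coalesced genealogies of the sampled haplotypes.

    Wraps the recapitated tree sequence together with the mapping from
    population rows to tree-sequence individuals.  ``ts.samples()`` holds
    two haplotype nodes per sampled individual, grouped by individual in
    the order of ``sample_rows``.
    """

    ts: tskit.TreeSequence
    sample_rows: np.ndarray  # population row index per sampled individual
    genome_length: float
    recomb_rate: float
    mode: str
    N_present: float

    @property
    def num_sample_haplotypes(self) -> int:
        return 2 * len(self.sample_rows)

    def fully_coalesced(self) -> bool:
        return all(tree.num_roots == 1 for tree in self.ts.trees())


@dataclass
class SiteSet:
    """Exactly ``m`` biallelic SNPs segregating in the sample.

    ``haplotypes`` is an ``m x 2n`` 0/1 matrix (two adjacent columns per
    individual, in ``sample_rows`` order); allele 1 at a site is the
    lexicographically larger of the two allele strings observed there.
    """

    m: int
    positions: np.ndarray
    haplotypes: np.ndarray
    sample_rows: np.ndarray
    final_mutation_rate: Optional[float] = None

    def __post_init__(self) -> None:
        if self.haplotypes.shape != (self.m, 2 * len(self.sample_rows)):
            raise ValueError("haplotype matrix shape mismatch")


def build_pedigree_tables(pop: PopulationState, sample_rows: Sequence[int]) -> tuple[tskit.TableCollection, np.ndarray]:
    """Extract the ancestor closure of ``sample_rows`` as msprime pedigree tables.

    Returns the table collection and the pedigree individual id of each
    sample row.  Node times are generations before the end of the spatial
    epoch (a sampled individual born earlier is a historical sample at its
    birth time, which is where its genome was formed).
    """
    sample_rows = np.asarray(sample_rows, dtype=np.int64)
    if sample_rows.size == 0:
        raise ValueError("no sample rows given")
    # vectorised ancestor closure, one generation of parents at a time
    needed = np.zeros(pop.size, dtype=bool)
    needed[sample_rows] = True
    frontier = sample_rows
    while frontier.size:
        parents = np.concatenate([pop.mother[frontier], pop.father[frontier]])
        parents = parents[parents >= 0]
        parents = parents[~needed[parents]]
        if parents.size == 0:
            break
        parents = np.unique(parents)
        needed[parents] = True
        frontier = parents
    rows = np.flatnonzero(needed)
    idmap = np.full(pop.size, -1, dtype=np.int32)
    idmap[rows] = np.arange(rows.size, dtype=np.int32)

    parents_col = np.full((rows.size, 2), -1, dtype=np.int32)
    for j, parent in enumerate((pop.mother, pop.father)):
        p = parent[rows]
        has = p >= 0
        parents_col[has, j] = idmap[p[has]]

    tables = tskit.TableCollection(sequence_length=float(pop.params.genome_length))
    tables.time_units = "generations"
    n_ind = rows.size
    tables.individuals.set_columns(
        flags=np.zeros(n_ind, dtype=np.uint32),
        parents=parents_col.reshape(-1).astype(np.int32),
        parents_offset=np.arange(0, 2 * n_ind + 1, 2, dtype=np.uint64),
    )
    times = (pop.time - pop.birth_step[rows]).astype(np.float64)
    is_samp = np.zeros(n_ind, dtype=bool)
    is_samp[idmap[sample_rows]] = True
    node_flags = np.where(np.repeat(is_samp, 2), tskit.NODE_IS_SAMPLE, 0).astype(np.uint32)
    tables.nodes.set_columns(
        flags=node_flags,
        time=np.repeat(times, 2),
        population=np.zeros(2 * n_ind, dtype=np.int32),
        individual=np.repeat(np.arange(n_ind, dtype=np.int32), 2),
    )
    tables.populations.metadata_schema = tskit.MetadataSchema.permissive_json()
    tables.populations.add_row({"name": "pop0", "description": "spatial population"})
    return tables, idmap[sample_rows]


def _demography(N_present: float, history: DemographicHistory) -> msprime.Demography:
    demog = msprime.Demography()
    demog.add_population(name="pop0", initial_size=N_present)
    if history.mode == "step" and history.N_anc_multiplier != 1.0:
        demog.add_population_parameters_change(
            time=history.change_time,
            initial_size=history.N_anc_multiplier * N_present,
            population="pop0",
        )
    return demog


def init_ancestral_diversity(
    pop: PopulationState,
    sample_rows: Sequence[int],
    history: Optional[DemographicHistory] = None,
    N_present: Optional[float] = None,
    mode: str = "unlinked",
    seed: int = 1,
) -> AncestryRecord:
    """Trace sampled lineages through the pedigree and coalesce the remainder.

    The ancestral (pre-spatial-epoch) phase is panmictic with size
    ``N_present`` (default: the final census), modified by ``history``.
    Raises if any tree fails to coalesce.
    """
    if mode not in ("linked", "unlinked"):
        raise ValueError("mode must be 'linked' or 'unlinked'")
    history = history or DemographicHistory()
    if N_present is None:
        N_present = float(pop.census)
    if not N_present > 0:
        raise ValueError("N_present must be > 0")
    rate = pop.params.recomb_rate
    sample_rows = np.asarray(sample_rows, dtype=np.int64)
    tables, ped_ids = build_pedigree_tables(pop, sample_rows)
    ped_ts = msprime.sim_ancestry(
        initial_state=tables,
        model="fixed_pedigree",
        recombination_rate=rate,
        random_seed=derive_seed(seed, 1),
    )
    # keep only the sampled individuals' ancestry, preserving epoch-boundary
    # roots; order haplotype pairs by the caller's sample_rows order
    samp_nodes = np.column_stack([2 * ped_ids, 2 * ped_ids + 1]).ravel().astype(np.int32)
    small = ped_ts.simplify(samples=samp_nodes, keep_input_roots=True)
    recap = msprime.sim_ancestry(
        initial_state=small,
        demography=_demography(N_present, history),
        recombination_rate=rate,
        random_seed=derive_seed(seed, 2),
    )
    record = AncestryRecord(
        ts=recap,
        sample_rows=sample_rows,
        genome_length=float(pop.params.genome_length),
        recomb_rate=rate,
        mode=mode,
        N_present=N_present,
    )
    if not record.fully_coalesced():
        raise RuntimeError("ancestral phase failed to coalesce all trees")
    return record


def overlay_mutations_until_m(record: AncestryRecord, m: int, seed: int = 1,
                              start_rate: float = 1e-15) -> SiteSet:
    """Overlay neutral mutations and return exactly ``m`` segregating SNPs.

    Mutations are added at ``start_rate`` and the rate escalates tenfold
    (keeping earlier mutations) until at least ``m`` biallelic sites
    segregate among the sampled haplotypes; a uniform subsample of ``m``
    such sites is returned.  In ``unlinked`` mode the subsample keeps SNPs
    at least ``genome_length/(2m)`` apart (RADseq-like spacing).
    """
    if m <= 0:
        raise ValueError("m must be positive")
    ts = record.ts
    rate = float(start_rate)
    round_i = 0
    while True:
        ts = msprime.sim_mutations(ts, rate=rate, random_seed=derive_seed(seed, 10 + round_i), keep=True)
        geno, positions = _biallelic_genotypes(ts)
        if geno.shape[0] >= m:
            break
        rate *= 10.0
        round_i += 1
        if rate > 1.0:
            raise RuntimeError("mutation-rate escalation exceeded 1 per bp")
    rng = np.random.default_rng(derive_seed(seed, 99))
    if record.mode == "unlinked":
        pick = _spaced_subsample(positions, m, record.genome_length / (2.0 * m), rng)
        if pick is None:  # cannot honour the spacing; fall back to uniform
            pick = np.sort(rng.choice(geno.shape[0], size=m, replace=False))
    else:
        pick = np.sort(rng.choice(geno.shape[0], size=m, replace=False))
    return SiteSet(m=m, positions=positions[pick], haplotypes=geno[pick],
                   sample_rows=record.sample_rows, final_mutation_rate=rate)


def _spaced_subsample(positions: np.ndarray, m: int, min_gap: float,
                      rng: np.random.Generator) -> Optional[np.ndarray]:
    """Uniform-random subsample of ``m`` indices with pairwise gaps >= min_gap.

    Greedy left-to-right thinning of a random permutation-ordering; returns
    None when the spacing cannot be satisfied.
    """
    order = rng.permutation(positions.size)
    ranked = np.full(positions.size, -1, dtype=np.int64)
    ranked[order] = np.arange(positions.size)
    by_pos = np.argsort(positions, kind="stable")
    # sweep positions left to right, keeping a site when it clears the gap
    # from the last kept site and, if over-subscribed, preferring earlier
    # entries of the random order on conflict via repeated passes
    for _ in range(4):
        kept: list[int] = []
        last = -np.inf
        for i in by_pos:
            if positions[i] >= last + min_gap:
                kept.append(i)
                last = positions[i]
        if len(kept) >= m:
            kept_arr = np.asarray(kept)
            chosen = kept_arr[np.argsort(ranked[kept_arr])][:m]
            return np.sort(chosen)
        min_gap /= 2.0
    return None


def _biallelic_genotypes(ts: tskit.TreeSequence) -> tuple[np.ndarray, np.ndarray]:
    """0/1 haplotype matrix and positions of sites biallelic in the sample.

    Allele 1 is the lexicographically larger of the two observed allele
    strings (multi-hit sites showing three or more alleles are dropped, as
    are sites monomorphic in the sample).
    """
    out = []
    pos = []
    for var in ts.variants():
        g = var.genotypes
        present = np.unique(g)
        alleles = [var.alleles[a] for a in present]
        if len(present) != 2 or None in alleles:
            continue
        # map so that the lexicographically larger allele string is 1
        a_sorted = sorted(alleles)
        hi = present[alleles.index(a_sorted[1])]
        out.append((g == hi).astype(np.uint8))
        pos.append(var.site.position)
    if not out:
        return np.empty((0, ts.num_samples), dtype=np.uint8), np.empty(0)
    return np.asarray(out), np.asarray(pos)


# -- explicit meiosis primitives -------------------------------------------

def sample_crossovers(genome_length: float, recomb_rate: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Sorted crossover positions: Poisson count, uniform locations."""
    k = rng.poisson(recomb_rate * genome_length)
    return np.sort(rng.uniform(0.0, genome_length, size=k))


def inherit_recombinant_haplotype(parent_haplotypes: tuple[np.ndarray, np.ndarray],
                                  positions: np.ndarray,
                                  genome_length: float,
                                  recomb_rate: float,
                                  rng: np.random.Generator) -> np.ndarray:
    """Form a gamete from a parent's two haplotypes.

    The gamete starts on a fairly chosen haplotype and alternates at each
    crossover; ``positions`` gives the coordinate of each entry of the
    haplotype vectors.  This is the meiosis model under which the ancestry
    of the spatial epoch is simulated.
    """
    h0, h1 = parent_haplotypes
    positions = np.asarray(positions, dtype=float)
    breaks = sample_crossovers(genome_length, recomb_rate, rng)
    start = rng.integers(2)
    # which haplotype each position falls on: parity of crossovers to its left
    which = (start + np.searchsorted(breaks, positions, side="right")) % 2
    return np.where(which == 0, h0, h1)
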