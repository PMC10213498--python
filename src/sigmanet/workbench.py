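"""End-to-end orchestration: simulate -> sample -> encode -> train -> score.

The fixture generator runs the full pipeline at desk scale and is the
package's own definition of its study conditions.  Two scales are built in:

``tiny``
    W=10, K=5, 100 spatial steps, m=500 SNPs, n=10 individuals, 30
    simulations with 2 samples each — smoke-test sized.
``small``
    W=15, K=5, 150 spatial steps, m=1000 SNPs, n=20 individuals, 300
    simulations with 4 samples each — a scaled-down analogue of the
    fixed-density baseline regime (only sigma varies; sigma_f = sigma_m =
    sigma_c drawn uniformly, the sigma/W ratios matching the full-scale
    study).  See docs/methods.md for the reasoning behind the scales.

Every simulation contributes several partially overlapping samples (the
window position is random, individuals are redrawn, and each sample gets
its own SNP subsample), which enlarges the training set cheaply; the
train/validation and train/test splits are made by simulation so no
simulation leaks across sides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .ancestry import DemographicHistory, init_ancestral_diversity, overlay_mutations_until_m
from .cnn import (TrainedModel, TrainingConfig, build_architecture, predict_sigma_batch,
                  train)
from .estimate import evaluate
from .preprocess import (SampleSpec, encode_genotypes, place_sampling_window,
                         sample_individuals, sampling_width, segregating_site_indices)
from .rng import derive_seed
from .simulate import (SimParams, effective_sigma, effective_sigma_se,
                       mean_inbreeding_Ne, run_spatial_epoch)

__all__ = [
    "PipelineConfig",
    "TrainingBundle",
    "generate_fixture_dataset",
    "train_on_bundle",
    "recovery_experiment",
    "sigma_c_sensitivity_experiment",
    "SCALES",
]


@dataclass
class PipelineConfig:
    """Parameter distributions and counts for one training-set generation."""

    sigma_range: tuple[float, float]
    K: float
    habitat_width: float
    T_spatial: int
    n: int
    num_snps: int
    sims: int
    samples_per_sim: int
    phased: bool = False
    width_fraction: float = 1.0
    demography: DemographicHistory = field(default_factory=DemographicHistory)
    genome_length: float = 2.5e7
    recomb_rate: float = 1e-8
    mode: str = "unlinked"
    snp_pool_factor: float = 2.0
    max_retries: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.sigma_range
        if not (0 < lo <= hi):
            raise ValueError("empty sigma range")
        if self.sims < 1 or self.samples_per_sim < 1:
            raise ValueError("need at least one simulation and one sample")

    @property
    def edge_crop(self) -> float:
        # fixed to the maximum simulated sigma for the whole set, so the
        # crop does not leak the per-simulation sigma to the sampler
        return self.sigma_range[1]

    @property
    def training_size(self) -> int:
        return self.sims * self.samples_per_sim


SCALES: dict[str, dict] = {
    "tiny": dict(sigma_range=(0.1, 0.7), K=5.0, habitat_width=10.0, T_spatial=100,
                 n=10, num_snps=500, sims=30, samples_per_sim=2),
    "small": dict(sigma_range=(0.15, 1.0), K=5.0, habitat_width=15.0, T_spatial=150,
                  n=20, num_snps=1000, sims=300, samples_per_sim=4),
}


@dataclass
class TrainingBundle:
    """In-memory training set plus its provenance manifest."""

    genotypes: np.ndarray      # (N, m, columns) int8
    widths: np.ndarray         # (N,)
    log_targets: np.ndarray    # (N,) log sigma_f
    groups: np.ndarray         # (N,) source-simulation index
    manifest: pd.DataFrame
    config: PipelineConfig

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(out / "bundle.npz", genotypes=self.genotypes,
                            widths=self.widths, log_targets=self.log_targets,
                            groups=self.groups)
        self.manifest.to_csv(out / "manifest.csv", index=False)
        cfg = asdict(self.config)
        cfg["demography"] = asdict(self.config.demography)
        (out / "config.json").write_text(json.dumps(cfg, indent=1))

    @classmethod
    def load(cls, out_dir: str | Path) -> "TrainingBundle":
        out = Path(out_dir)
        with np.load(out / "bundle.npz") as z:
            arrays = {k: z[k] for k in z.files}
        cfg = json.loads((out / "config.json").read_text())
        cfg["demography"] = DemographicHistory(**cfg["demography"])
        cfg["sigma_range"] = tuple(cfg["sigma_range"])
        return cls(genotypes=arrays["genotypes"], widths=arrays["widths"],
                   log_targets=arrays["log_targets"], groups=arrays["groups"],
                   manifest=pd.read_csv(out / "manifest.csv"),
                   config=PipelineConfig(**cfg))


def _simulate_one(config: PipelineConfig, sim_index: int) -> tuple:
    """One non-extinct simulation (with retries) and its drawn sigma."""
    retries = 0
    while True:
        seed = derive_seed(config.seed, 1, sim_index, retries)
        rng = np.random.default_rng(seed)
        sigma = rng.uniform(*config.sigma_range)
        params = SimParams(sigma_f=sigma, sigma_m=sigma, sigma_c=sigma,
                           K=config.K, W=config.habitat_width,
                           T_spatial=config.T_spatial,
                           genome_length=config.genome_length,
                           recomb_rate=config.recomb_rate, seed=seed)
        pop = run_spatial_epoch(params)
        if pop.extinct_at is None:
            return pop, sigma, seed, retries
        retries += 1
        if retries > config.max_retries:
            raise RuntimeError(
                f"simulation {sim_index} went extinct {retries} times in a row")


def generate_fixture_dataset(scale: str | PipelineConfig = "tiny", seed: int = 0,
                             out_dir: Optional[str | Path] = None) -> TrainingBundle:
    """Run the simulate/sample/encode pipeline and collect a training bundle.

    Extinct replicates are logged in the manifest retry column and
    resampled with a fresh seed (up to the retry cap).  The same seed
    always reproduces the identical bundle.
    """
    if isinstance(scale, PipelineConfig):
        config = scale
    else:
        if scale not in SCALES:
            raise ValueError(f"unknown scale {scale!r}; options: {sorted(SCALES)}")
        config = PipelineConfig(seed=seed, **SCALES[scale])

    genos, widths, targets, groups, rows = [], [], [], [], []
    for s in range(config.sims):
        pop, sigma, sim_seed, retries = _simulate_one(config, s)
        draw_rng = np.random.default_rng(derive_seed(config.seed, 2, s))
        spec = SampleSpec(n=config.n, width_fraction=config.width_fraction,
                          edge_crop=config.edge_crop, seed=int(sim_seed))
        window_rows = []
        for k in range(config.samples_per_sim):
            window = place_sampling_window(config.habitat_width, spec, draw_rng)
            window_rows.append(sample_individuals(pop, window, spec, draw_rng))
        union = np.unique(np.concatenate(window_rows))
        record = init_ancestral_diversity(pop, union, history=config.demography,
                                          mode=config.mode,
                                          seed=derive_seed(config.seed, 3, s))
        pool_m = int(np.ceil(config.snp_pool_factor * config.num_snps))
        pool = overlay_mutations_until_m(record, pool_m,
                                         seed=derive_seed(config.seed, 4, s))
        eff_sig = effective_sigma(pop)
        nei = mean_inbreeding_Ne(pop)
        for k, sample in enumerate(window_rows):
            seg = segregating_site_indices(pool, sample)
            if seg.size < config.num_snps:
                raise RuntimeError(
                    f"sim {s} sample {k}: only {seg.size} segregating sites "
                    f"in the subsample; increase snp_pool_factor")
            pick = np.sort(draw_rng.choice(seg, size=config.num_snps, replace=False))
            sub = type(pool)(m=config.num_snps, positions=pool.positions[pick],
                             haplotypes=pool.haplotypes[pick],
                             sample_rows=pool.sample_rows)
            gm = encode_genotypes(sample, sub, phased=config.phased,
                                  pad_to=None, rng=draw_rng)
            loc = np.column_stack([pop.x[sample], pop.y[sample]])
            width = sampling_width(loc, metric="euclidean")
            genos.append(gm.values.astype(np.int8))
            widths.append(width)
            targets.append(np.log(sigma))
            groups.append(s)
            rows.append(dict(sim=s, sample=k, seed=sim_seed, retries=retries,
                             sigma_f=sigma, effective_sigma=eff_sig,
                             census=pop.census, mean_NeI=nei,
                             sampling_width=width, n=config.n,
                             m=config.num_snps))
    bundle = TrainingBundle(genotypes=np.asarray(genos, dtype=np.int8),
                            widths=np.asarray(widths),
                            log_targets=np.asarray(targets),
                            groups=np.asarray(groups),
                            manifest=pd.DataFrame(rows), config=config)
    if out_dir is not None:
        bundle.save(out_dir)
    return bundle


def train_on_bundle(bundle: TrainingBundle, patience: int = 20,
                    seed: int = 0, dropout: float = 0.0,
                    batch_size: int = 40,
                    subset: Optional[np.ndarray] = None) -> TrainedModel:
    """Derive the architecture from the bundle and fit the CNN."""
    idx = np.arange(bundle.genotypes.shape[0]) if subset is None else np.asarray(subset)
    cols = bundle.genotypes.shape[2]
    spec = build_architecture(bundle.config.num_snps, cols,
                              phased=bundle.config.phased, dropout=dropout)
    cfg = TrainingConfig(patience=patience, dropout=dropout, seed=seed,
                         batch_size=batch_size)
    return train(spec, bundle.genotypes[idx], bundle.widths[idx],
                 bundle.log_targets[idx], cfg, groups=bundle.groups[idx])


def recovery_experiment(bundle: TrainingBundle, holdout_fraction: float = 0.15,
                        patience: int = 20, seed: int = 0,
                        batch_size: int = 40) -> dict:
    """Train on most simulations, score parameter recovery on the rest.

    The held-out simulations never contribute a sample to training.  Each
    held-out simulation is one test dataset: its estimate is the mean of
    the CNN predictions over that simulation's replicate samples (the same
    replicate-averaging used when reporting bootstrap means), and MRAE and
    the Pearson correlation against true sigma (training-target
    convention, sigma_f) are computed across simulations.  Per-sample
    metrics are returned alongside for reference.
    """
    rng = np.random.default_rng(derive_seed(seed, 77))
    sims = np.unique(bundle.groups)
    n_hold = max(1, int(round(holdout_fraction * sims.size)))
    held = rng.choice(sims, size=n_hold, replace=False)
    test_mask = np.isin(bundle.groups, held)
    model = train_on_bundle(bundle, patience=patience, seed=seed,
                            batch_size=batch_size,
                            subset=np.flatnonzero(~test_mask))
    te = np.flatnonzero(test_mask)
    sample_preds = predict_sigma_batch(model, bundle.genotypes[te],
                                       bundle.widths[te])
    sample_truth = np.exp(bundle.log_targets[te])
    preds = np.array([sample_preds[bundle.groups[te] == s].mean() for s in held])
    truth = np.array([sample_truth[bundle.groups[te] == s][0] for s in held])
    report = evaluate(preds, truth)
    r = float(np.corrcoef(preds, truth)[0, 1])
    sample_report = evaluate(sample_preds, sample_truth)
    return dict(model=model, mrae=report.mrae, pearson_r=r,
                predictions=preds, truths=truth, held_out_sims=held,
                sample_mrae=sample_report.mrae,
                sample_pearson_r=float(np.corrcoef(sample_preds, sample_truth)[0, 1]))


def sigma_c_sensitivity_experiment(seed: int = 0, sigma: float = 1.0,
                                   sigma_c_low: float = 0.25, factor: float = 10.0,
                                   W: float = 20.0, K: float = 5.0,
                                   T_spatial: int = 150, reps: int = 2) -> dict:
    """Effect of a ``factor``-fold change in sigma_c on tracked effective sigma.

    Runs paired simulations (same seed per pair) with sigma_f = sigma_m
    fixed and sigma_c at ``sigma_c_low`` versus ``factor`` times it, and
    reports the mean relative difference in the tracked effective dispersal
    beyond twice the combined Monte-Carlo standard error, as a percentage.
    """
    beyond, rel, births = [], [], 0
    for r in range(reps):
        pair_seed = derive_seed(seed, 31, r)
        est = []
        for sc in (sigma_c_low, sigma_c_low * factor):
            params = SimParams(sigma_f=sigma, sigma_m=sigma, sigma_c=sc,
                               K=K, W=W, T_spatial=T_spatial, seed=pair_seed)
            pop = run_spatial_epoch(params)
            if pop.extinct_at is not None:
                raise RuntimeError("sensitivity run went extinct; not a stable range")
            est.append((effective_sigma(pop), effective_sigma_se(pop)))
            births += int(pop.dispersal_sum_f)
        (lo, se_lo), (hi, se_hi) = est
        rdiff = abs(hi - lo) / lo
        mc = 2.0 * float(np.hypot(se_lo, se_hi)) / lo
        rel.append(rdiff)
        beyond.append(max(0.0, rdiff - mc))
    return dict(percent_beyond_mc=100.0 * float(np.mean(beyond)),
                percent_raw=100.0 * float(np.mean(rel)),
                weighted_births=births, reps=reps)
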