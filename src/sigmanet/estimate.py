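"""Bootstrap-over-SNPs uncertainty, inflated intervals, diagnostics, scoring.

A trained network gives one dispersal estimate per draw of ``m`` SNPs from
the available pool; the spread across replicate draws reflects the
genealogical noise between subsets of loci.  The middle 95% of the
bootstrap distribution, inflated about the mean by a calibration factor
(3.8 for the reference training regime — an empirically derived value that
is not guaranteed to transfer to other networks), serves as an approximate
credible interval.  A Mahalanobis distance between a dataset's summary
statistics and the training distribution flags out-of-distribution inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .ancestry import SiteSet
from .cnn import TrainedModel, correct_sigma, predict_sigma_batch
from .preprocess import encode_genotypes, segregating_site_indices

__all__ = [
    "EstimateResult",
    "EvalReport",
    "bootstrap_predict",
    "inflated_interval",
    "inflate_from_quantiles",
    "mahalanobis_distance",
    "evaluate",
    "DEFAULT_INFLATION",
]

DEFAULT_INFLATION = 3.8


@dataclass
class EstimateResult:
    """Point estimate with bootstrap distribution and intervals."""

    point: float                 # mean of the bootstrap estimates
    estimates: np.ndarray        # all B estimates
    raw_interval: tuple[float, float]      # 2.5% / 97.5% quantiles (a, b)
    interval: tuple[float, float]          # inflated interval
    inflation: float
    B: int
    m: int


@dataclass
class EvalReport:
    """Per-replicate relative absolute errors and their mean."""

    rae: np.ndarray
    mrae: float
    n_undefined: int


def inflate_from_quantiles(point: float, a: float, b: float,
                           inflation: float = DEFAULT_INFLATION) -> tuple[float, float]:
    """``[max(0, s - infl*(s-a)), s + infl*(b-s)]`` for mean s, quantiles a, b."""
    return (max(0.0, point - inflation * (point - a)),
            point + inflation * (b - point))


def inflated_interval(estimates: Sequence[float],
                      inflation: float = DEFAULT_INFLATION) -> tuple[float, float]:
    """Credible interval: percentile interval widened about the mean.

    With ``s`` the mean of the estimates and (a, b) the 2.5%/97.5%
    quantiles (linear interpolation), returns
    ``[max(0, s - inflation*(s - a)), s + inflation*(b - s)]``; the left
    endpoint is clamped at 0 since dispersal is positive.
    """
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("no estimates")
    s = float(est.mean())
    a, b = np.quantile(est, [0.025, 0.975])
    lo, hi = inflate_from_quantiles(s, float(a), float(b), inflation)
    return (float(lo), float(hi))


def bootstrap_predict(model: TrainedModel, snp_pool: SiteSet,
                      sample_rows: Sequence[int], m: int, B: int,
                      rng: np.random.Generator,
                      inflation: float = DEFAULT_INFLATION,
                      width: Optional[float] = None,
                      apply_correction: Optional[bool] = None) -> EstimateResult:
    """Predict from ``B`` independent draws of ``m`` SNPs.

    Each replicate draws ``m`` sites without replacement from the pool of
    sites segregating in the sample (replicates are independent, so draws
    may overlap between replicates), re-encodes the genotype matrix, and
    predicts.  The ``sqrt(3/2)`` correction is applied when the model was
    trained on ``log_sigma_f`` targets (override with ``apply_correction``).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    seg = segregating_site_indices(snp_pool, sample_rows)
    if seg.size < m:
        raise ValueError(f"SNP pool has only {seg.size} usable sites, need m={m}")
    if width is None:
        raise ValueError("sampling width is required")
    if apply_correction is None:
        apply_correction = model.target_convention == "log_sigma_f"
    mats = []
    for _ in range(B):
        pick = rng.choice(seg, size=m, replace=False)
        pick.sort()
        sub = SiteSet(m=m, positions=snp_pool.positions[pick],
                      haplotypes=snp_pool.haplotypes[pick],
                      sample_rows=snp_pool.sample_rows)
        gm = encode_genotypes(sample_rows, sub, phased=model.spec.phased,
                              pad_to=model.spec.pad_to, rng=rng)
        mats.append(gm.values)
    ests = predict_sigma_batch(model, np.asarray(mats), np.full(B, width))
    if apply_correction:
        ests = correct_sigma(ests)
    point = float(np.mean(ests))
    a, b = (np.quantile(ests, [0.025, 0.975]) if B > 1 else (ests[0], ests[0]))
    return EstimateResult(point=point, estimates=np.asarray(ests),
                          raw_interval=(float(a), float(b)),
                          interval=inflated_interval(ests, inflation),
                          inflation=inflation, B=B, m=m)


def mahalanobis_distance(x: np.ndarray, centroid: np.ndarray,
                         covariance: np.ndarray) -> float:
    """``D = sqrt((x - mu)^T C^-1 (x - mu))`` for positive-definite C."""
    x = np.asarray(x, dtype=float)
    mu = np.asarray(centroid, dtype=float)
    C = np.asarray(covariance, dtype=float)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        raise ValueError(
            "covariance is singular or not positive-definite; consider "
            "regularising it (e.g. add a small ridge to the diagonal)")
    z = np.linalg.solve(L, x - mu)
    return float(np.sqrt(z @ z))


def evaluate(estimates: Sequence[float], truths: Sequence[float]) -> EvalReport:
    """Relative absolute error per replicate and its mean (MRAE).

    Undefined estimates (NaN) are counted separately and do not contribute
    to the MRAE.
    """
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape:
        raise ValueError("estimates and truths must have equal length")
    if np.any(tru <= 0):
        raise ValueError("truths must be positive")
    defined = np.isfinite(est)
    rae = np.abs(est[defined] - tru[defined]) / tru[defined]
    mrae = float(rae.mean()) if rae.size else float("nan")
    return EvalReport(rae=rae, mrae=mrae, n_undefined=int((~defined).sum()))
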