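"""Haploid linkage-disequilibrium statistics and LD-decay estimation.

For pairs of biallelic SNP loci on the same contig, this module
computes the classical two-locus statistics from observed haplotype
frequencies:

    D   = p_AB - p_A p_B                    (haplotype covariance)
    D'  = |D| / D_max                        in [0, 1]
    r^2 = D^2 / (p_A(1-p_A) p_B(1-p_B))      in [0, 1]

with D_max = min(p_A(1-p_B), (1-p_A)p_B) when D > 0 and
min(p_A p_B, (1-p_A)(1-p_B)) when D < 0 (D' = 0 when D = 0).
Because genomes are haploid, haplotypes are observed directly — no
phasing or EM is needed.

LD decay is summarized two ways, as in LD-decay plots of statistic vs
inter-locus distance:

* the decay *interval* from arithmetic bin means: with M the maximum
  bin mean and H = M/2, the left border is the first (smallest
  distance) bin whose mean drops below H and the right border the last
  bin whose mean is still above H;
* the decay *distance* from a fitted smooth curve: the smallest
  distance at which the curve crosses half of the maximum observed
  statistic from above (the midpoint of an LD-decay figure).  The
  default smoother is a GAM-style cubic smoothing spline whose penalty
  is chosen by generalized cross-validation (one fit per dataset, no
  tuning); a local-quadratic LOESS (tricube weights) is available as
  an alternative, and any monotone-capable smoother can be plugged in,
  as the half-max crossing contract does not depend on the smoother.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import brentq

from .variants import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


class UndefinedLDError(ValueError):
    """LD is undefined (a locus is monomorphic among complete samples)."""


class InsufficientDataError(ValueError):
    """Too few pairs to fit a decay curve."""


@dataclasses.dataclass
class LDResult:
    """Two-locus LD statistics for one pair of biallelic loci."""

    locus_i: int
    locus_j: int
    distance: int
    D: float
    D_prime: float
    r2: float


@dataclasses.dataclass
class BinnedSeries:
    """Arithmetic means of an LD statistic per distance bin.

    Bins are (0, w], (w, 2w], ...; a pair at distance exactly w falls
    in the first bin.  `distances` holds each bin's representative
    distance (the bin's upper edge); empty bins are omitted.
    """

    bin_width: int
    distances: np.ndarray
    means: np.ndarray
    counts: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.distances)


@dataclasses.dataclass
class DecayEstimate:
    """Decay-interval borders and fitted-curve decay distance."""

    bin_width: int
    max_mean: float
    half_max: float
    left_border: float | None
    right_border: float | None
    decay_distance: float | None
    censored: bool


# ---------------------------------------------------------------------------
# locus selection and per-pair statistics
# ---------------------------------------------------------------------------

def biallelic_loci(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Restrict to loci with exactly two distinct observed alleles.

    Monomorphic and tri-/tetra-allelic loci (among non-missing calls)
    are dropped; surviving calls are recoded 0/1 (0 = the smaller of
    the two observed allele codes) and the locus REF/ALT fields updated
    to the two observed alleles.
    """
    keep: list[int] = []
    recoded_cols: list[np.ndarray] = []
    new_loci = []
    for j, loc in enumerate(matrix.loci):
        col = matrix.calls[:, j]
        obs = np.unique(col[col != MISSING])
        if len(obs) != 2:
            continue
        a0, a1 = int(obs[0]), int(obs[1])
        new_col = np.full_like(col, MISSING)
        new_col[col == a0] = 0
        new_col[col == a1] = 1
        alleles = (loc.ref,) + loc.alts
        new_loci.append(
            loc._replace(ref=alleles[a0], alts=(alleles[a1],))
        )
        keep.append(j)
        recoded_cols.append(new_col)
    calls = (
        np.stack(recoded_cols, axis=1)
        if recoded_cols
        else np.zeros((matrix.n_samples, 0), dtype=np.int16)
    )
    return GenotypeMatrix(
        sample_ids=list(matrix.sample_ids),
        loci=new_loci,
        calls=calls,
        contigs=list(matrix.contigs) if matrix.contigs else None,
    )


def pair_ld(matrix: GenotypeMatrix, i: int, j: int) -> LDResult:
    """D, D' and r^2 for the biallelic locus pair (i, j).

    Samples missing a call at either locus are excluded; allele 1 at
    each locus plays the role of A/B in the formulas (the statistics
    D' and r^2 are invariant under allele relabeling; D changes sign).
    Raises :class:`UndefinedLDError` if either locus is monomorphic
    among the complete samples, and ValueError for inter-contig pairs.
    """
    li, lj = matrix.loci[i], matrix.loci[j]
    if li.contig != lj.contig:
        raise ValueError("LD is defined only for loci on the same contig")
    ci, cj = matrix.calls[:, i], matrix.calls[:, j]
    ok = (ci != MISSING) & (cj != MISSING)
    a, b = ci[ok].astype(float), cj[ok].astype(float)
    n = a.size
    if n == 0 or len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        raise UndefinedLDError(
            f"monomorphic locus among complete samples for pair ({i}, {j})"
        )
    pA = a.mean()
    pB = b.mean()
    pAB = float(np.mean(a * b))
    D = pAB - pA * pB
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = abs(D) / dmax if D != 0 else 0.0
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return LDResult(
        locus_i=i,
        locus_j=j,
        distance=abs(lj.pos - li.pos),
        D=D,
        D_prime=float(d_prime),
        r2=float(r2),
    )


def enumerate_pairs(
    matrix: GenotypeMatrix, max_distance: int = 10_000
) -> Iterator[LDResult]:
    """All same-contig biallelic locus pairs within `max_distance` bp.

    Yields each pair once (1 <= |pos_j - pos_i| <= max_distance); pairs
    whose statistics are undefined after missing-data exclusion are
    skipped and counted in a log message.
    """
    n = matrix.n_loci
    skipped = 0
    for i in range(n):
        li = matrix.loci[i]
        for j in range(i + 1, n):
            lj = matrix.loci[j]
            if lj.contig != li.contig:
                break
            dist = lj.pos - li.pos
            if dist > max_distance:
                break
            if dist < 1:
                continue
            try:
                yield pair_ld(matrix, i, j)
            except UndefinedLDError:
                skipped += 1
    if skipped:
        logger.info("enumerate_pairs: skipped %d undefined pairs", skipped)


# ---------------------------------------------------------------------------
# binning and the decay interval
# ---------------------------------------------------------------------------

def bin_means(
    results: Iterable[LDResult],
    statistic: str = "r2",
    bin_width: int = 100,
) -> BinnedSeries:
    """Arithmetic mean of `statistic` ('r2' or 'D_prime') per distance bin."""
    if statistic not in {"r2", "D_prime"}:
        raise ValueError("statistic must be 'r2' or 'D_prime'")
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for res in results:
        b = int(math.ceil(res.distance / bin_width))
        sums[b] = sums.get(b, 0.0) + getattr(res, statistic)
        counts[b] = counts.get(b, 0) + 1
    bins = sorted(sums)
    return BinnedSeries(
        bin_width=bin_width,
        distances=np.array([b * bin_width for b in bins], dtype=float),
        means=np.array([sums[b] / counts[b] for b in bins]),
        counts=np.array([counts[b] for b in bins], dtype=np.int64),
    )


def decay_interval(
    binned: BinnedSeries,
) -> tuple[float | None, float | None, float, float]:
    """Decay-interval borders from bin means.

    With M the maximum bin mean and H = M/2: the left border is the
    distance of the first bin whose mean is strictly below H (None when
    every mean stays above H — censored) and the right border the
    distance of the last bin whose mean is strictly above H.
    Returns (left_border, right_border, M, H).
    """
    if binned.n_bins == 0:
        raise ValueError("empty binned series")
    M = float(binned.means.max())
    H = M / 2.0
    below = np.nonzero(binned.means < H)[0]
    above = np.nonzero(binned.means > H)[0]
    left = float(binned.distances[below[0]]) if below.size else None
    right = float(binned.distances[above[-1]]) if above.size else None
    return left, right, M, H


# ---------------------------------------------------------------------------
# LOESS fit and the decay distance
# ---------------------------------------------------------------------------

def _loess_fit(
    x: np.ndarray, y: np.ndarray, span: float, degree: int = 2
) -> Callable[[float], float]:
    """Local polynomial (default quadratic) regression with tricube
    weights over the `span` fraction of nearest neighbors."""
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    n = len(xs)
    k = max(int(math.ceil(span * n)), degree + 2)
    k = min(k, n)

    def f(x0: float) -> float:
        d = np.abs(xs - x0)
        idx = np.argpartition(d, k - 1)[:k]
        dmax = d[idx].max()
        if dmax == 0:
            return float(np.mean(ys[idx]))
        w = (1 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 0, None)
        dx = xs[idx] - x0
        cols = [np.ones_like(dx)]
        for p in range(1, degree + 1):
            cols.append(dx**p)
        A = np.stack(cols, axis=1)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(A * sw[:, None], ys[idx] * sw, rcond=None)
        return float(beta[0])

    return f


def _gam_fit(x: np.ndarray, y: np.ndarray) -> Callable[[float], float]:
    """GAM-style cubic smoothing spline, penalty chosen by GCV.

    Repeated distances are collapsed to weighted means (weights
    normalized to mean 1, so duplicating every observation leaves the
    fit unchanged).
    """
    ux, inv = np.unique(x, return_inverse=True)
    w = np.bincount(inv).astype(float)
    uy = np.bincount(inv, weights=y) / w
    if len(ux) < 4:
        # too few distinct distances for a cubic spline: constant fit
        mean = float(np.average(uy, weights=w))
        return lambda t: mean
    w = w / w.mean()
    spl = make_smoothing_spline(ux, uy, w=w)
    return lambda t: float(spl(t))


def fit_decay_curve(
    results: Sequence[LDResult],
    statistic: str = "r2",
    smoother: str = "gam",
    span: float = 0.5,
    min_pairs: int = 20,
    max_distance: int | None = None,
    grid_points: int = 200,
) -> tuple[Callable[[float], float], float | None, bool]:
    """Fitted decay curve and half-max decay distance.

    Fits the chosen statistic against inter-locus distance with the
    selected smoother ('gam' = GCV smoothing spline, the default;
    'loess' = local quadratic with `span`) and locates the decay
    distance: the smallest distance at which the fitted curve crosses
    H from above, where H is half of the fitted curve's maximum (the
    half-max reference line of an LD-decay plot).  The crossing is
    sought from the curve's maximum onward, bracketed on an evaluation
    grid and refined by root bisection.  Returns (fitted function,
    decay_distance, censored); censored is True when the curve never
    falls below half of its maximum within the distance window (no
    decay detectable), in which case decay_distance is None.
    """
    if statistic not in {"r2", "D_prime"}:
        raise ValueError("statistic must be 'r2' or 'D_prime'")
    results = list(results)
    if len(results) < min_pairs:
        raise InsufficientDataError(
            f"need at least {min_pairs} pairs, got {len(results)}"
        )
    x = np.array([r.distance for r in results], dtype=float)
    y = np.array([getattr(r, statistic) for r in results], dtype=float)
    if smoother == "gam":
        f = _gam_fit(x, y)
    elif smoother == "loess":
        f = _loess_fit(x, y, span=span)
    else:
        raise ValueError("smoother must be 'gam' or 'loess'")
    hi = float(max_distance) if max_distance is not None else float(x.max())
    lo = float(x.min())
    grid = np.linspace(lo, hi, grid_points)
    vals = np.array([f(g) for g in grid])
    H = float(vals.max()) / 2.0
    start = int(np.argmax(vals))
    decay = None
    for a, b, va, vb in zip(
        grid[start:], grid[start + 1 :], vals[start:], vals[start + 1 :]
    ):
        if va >= H > vb:
            if va == H:
                decay = float(a)
            else:
                decay = float(brentq(lambda t: f(t) - H, a, b, xtol=1e-6))
            break
    return f, decay, decay is None


def decay_summary(
    results: Sequence[LDResult],
    statistic: str = "r2",
    bin_width: int = 100,
    smoother: str = "gam",
    span: float = 0.5,
    max_distance: int | None = None,
    min_pairs: int = 20,
) -> DecayEstimate:
    """Bin, locate the decay interval, fit the curve, and bundle the
    full decay estimate for one statistic."""
    results = list(results)
    binned = bin_means(results, statistic=statistic, bin_width=bin_width)
    left, right, M, H = decay_interval(binned)
    _, decay, censored = fit_decay_curve(
        results,
        statistic=statistic,
        smoother=smoother,
        span=span,
        max_distance=max_distance,
        min_pairs=min_pairs,
    )
    return DecayEstimate(
        bin_width=bin_width,
        max_mean=M,
        half_max=H,
        left_border=left,
        right_border=right,
        decay_distance=decay,
        censored=censored,
    )
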