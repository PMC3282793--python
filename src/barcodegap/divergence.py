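"""Intra/inter-specific divergence: metrics, rank tests, barcoding-gap histograms.

Every unordered sample pair with a defined distance is either intraspecific
(same species label) or interspecific. Six summary metrics are computed:

=================  ============================================================
all_intra          mean +/- SD over all intraspecific pair distances
mean_theta         per-species mean intraspecific distance (theta), averaged
                   across species with >=2 samples
coalescent_depth   per-species maximum intraspecific distance (the deepest
                   split of an ultrametric cluster equals the max pairwise
                   distance, so no tree is built), averaged across species
all_inter          mean +/- SD over all interspecific pair distances
theta_prime        per-species mean distance to heterospecific samples,
                   averaged across species
min_inter          per-species minimum distance to any heterospecific sample,
                   averaged across species
=================  ============================================================

SDs are sample SDs (n-1 denominator; n=1 gives SD 0). A metric with empty
support is reported as missing, never as 0.

Rank tests (signed-rank for the same pair-set scored at two loci, rank-sum
for intra vs inter distributions) use midranks for ties. p-values are exact
(full conditional permutation distribution) for small samples and use the
normal approximation with tie and continuity corrections otherwise; at the
scale of real barcode datasets (thousands of pairs) the approximation path
is always taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .distances import DistanceMatrix
from .errors import DegenerateTestError, InsufficientDataError

__all__ = [
    "METRICS",
    "PairPartition",
    "MetricSummary",
    "DivergenceSummary",
    "WilcoxonResult",
    "RankSumResult",
    "GapHistogram",
    "partition_pairs",
    "divergence_summary",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "paired_inter_distances",
    "gap_histogram",
]

METRICS = (
    "all_intra",
    "mean_theta",
    "coalescent_depth",
    "all_inter",
    "theta_prime",
    "min_inter",
)


@dataclass
class PairPartition:
    """All defined sample pairs split into intra- and inter-specific sets."""

    intra_pairs: list[tuple[str, str, float]]
    inter_pairs: list[tuple[str, str, float]]
    species_of: dict[str, str]
    n_samples: int
    n_excluded: int  # pairs with flagged-missing distances

    @property
    def intra_distances(self) -> np.ndarray:
        return np.array([d for _, _, d in self.intra_pairs])

    @property
    def inter_distances(self) -> np.ndarray:
        return np.array([d for _, _, d in self.inter_pairs])


def partition_pairs(dm: DistanceMatrix) -> PairPartition:
    """Split every defined unordered pair of ``dm`` by species identity."""
    intra: list[tuple[str, str, float]] = []
    inter: list[tuple[str, str, float]] = []
    excluded = 0
    n = dm.n
    for i in range(n):
        for j in range(i + 1, n):
            d = dm.values[i, j]
            if not np.isfinite(d):
                excluded += 1
                continue
            rec = (dm.labels[i], dm.labels[j], float(d))
            if dm.species[i] == dm.species[j]:
                intra.append(rec)
            else:
                inter.append(rec)
    return PairPartition(
        intra_pairs=intra,
        inter_pairs=inter,
        species_of=dict(zip(dm.labels, dm.species)),
        n_samples=n,
        n_excluded=excluded,
    )


@dataclass(frozen=True)
class MetricSummary:
    mean: float
    sd: float
    n: int


def _summarize(values: Sequence[float]) -> MetricSummary | None:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return None
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return MetricSummary(mean=float(arr.mean()), sd=sd, n=int(arr.size))


@dataclass
class DivergenceSummary:
    """The six divergence metrics; a metric with no support maps to None."""

    metrics: dict[str, MetricSummary | None]
    locus: str = ""

    def __getitem__(self, name: str) -> MetricSummary | None:
        return self.metrics[name]

    def to_rows(self) -> list[dict]:
        rows = []
        for name in METRICS:
            m = self.metrics[name]
            rows.append(
                {
                    "locus": self.locus,
                    "metric": name,
                    "mean": None if m is None else m.mean,
                    "sd": None if m is None else m.sd,
                    "n": 0 if m is None else m.n,
                }
            )
        return rows


def divergence_summary(part: PairPartition, locus: str = "") -> DivergenceSummary:
    """Compute the six intra/inter divergence metrics from a pair partition."""
    by_species_intra: dict[str, list[float]] = {}
    for a, b, d in part.intra_pairs:
        by_species_intra.setdefault(part.species_of[a], []).append(d)
    by_species_hetero: dict[str, list[float]] = {}
    for a, b, d in part.inter_pairs:
        by_species_hetero.setdefault(part.species_of[a], []).append(d)
        by_species_hetero.setdefault(part.species_of[b], []).append(d)

    species_order = sorted({part.species_of[s] for s in part.species_of})
    theta = [np.mean(by_species_intra[sp]) for sp in species_order if sp in by_species_intra]
    depth = [np.max(by_species_intra[sp]) for sp in species_order if sp in by_species_intra]
    theta_prime = [
        np.mean(by_species_hetero[sp]) for sp in species_order if sp in by_species_hetero
    ]
    min_inter = [
        np.min(by_species_hetero[sp]) for sp in species_order if sp in by_species_hetero
    ]

    return DivergenceSummary(
        metrics={
            "all_intra": _summarize([d for _, _, d in part.intra_pairs]),
            "mean_theta": _summarize(theta),
            "coalescent_depth": _summarize(depth),
            "all_inter": _summarize([d for _, _, d in part.inter_pairs]),
            "theta_prime": _summarize(theta_prime),
            "min_inter": _summarize(min_inter),
        },
        locus=locus,
    )


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

# largest sample sizes for which the exact conditional permutation
# distribution is computed instead of the normal approximation
EXACT_SIGNED_RANK_MAX_N = 25
EXACT_RANK_SUM_MAX_N = 20


@dataclass(frozen=True)
class WilcoxonResult:
    w_plus: float
    w_minus: float
    n_used: int
    p_value: float
    direction: str  # "a>b", "b>a" or "none"
    method: str     # "exact" or "approx"


@dataclass(frozen=True)
class RankSumResult:
    rank_sum_a: float
    u_a: float
    n_a: int
    n_b: int
    p_value: float
    direction: str
    method: str


def _two_sided_from_counts(counts: np.ndarray, observed_scaled: int) -> float:
    """Two-sided p = 2*min(P(W<=w), P(W>=w)) from an integer-support pmf."""
    total = counts.sum()
    lo = counts[: observed_scaled + 1].sum() / total
    hi = counts[observed_scaled:].sum() / total
    return float(min(1.0, 2.0 * min(lo, hi)))


def _signed_rank_exact_p(ranks2: np.ndarray, w_plus2: int) -> float:
    """Distribution of 2*W+ over all 2^n sign assignments, by polynomial DP."""
    counts = np.zeros(int(ranks2.sum()) + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return _two_sided_from_counts(counts, w_plus2)


def _rank_sum_exact_p(ranks2: np.ndarray, n_a: int, w_a2: int) -> float:
    """Distribution of 2*W_a over all C(N, n_a) group assignments."""
    sums = np.fromiter(
        (sum(c) for c in combinations(ranks2.tolist(), n_a)), dtype=np.int64
    )
    counts = np.bincount(sums, minlength=int(ranks2.sum()) + 1).astype(float)
    return _two_sided_from_counts(counts, w_a2)


def wilcoxon_signed_rank(
    paired_a: Sequence[float], paired_b: Sequence[float], method: str = "auto"
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped; ties in |difference| receive midranks. The
    two-sided p-value is exact for ``n_used`` <= 25 (method="auto") and a
    tie-corrected normal approximation with continuity correction otherwise.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired lists must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateTestError("all paired differences are zero")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())

    if method == "auto":
        method = "exact" if n <= EXACT_SIGNED_RANK_MAX_N else "approx"
    if method == "exact":
        ranks2 = np.round(2 * ranks).astype(np.int64)  # midranks are halves
        p = _signed_rank_exact_p(ranks2, int(round(2 * w_plus)))
    elif method == "approx":
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts) / 48.0).sum())
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        if sigma == 0:
            raise DegenerateTestError("zero variance after tie correction")
        z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / sigma
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    else:
        raise ValueError(f"unknown method {method!r}")

    direction = "a>b" if w_plus > w_minus else ("b>a" if w_minus > w_plus else "none")
    return WilcoxonResult(w_plus, w_minus, n, p, direction, method)


def wilcoxon_rank_sum(
    sample_a: Sequence[float], sample_b: Sequence[float], method: str = "auto"
) -> RankSumResult:
    """Wilcoxon rank-sum (Mann-Whitney) test on two independent samples.

    Midranks for ties; exact p for pooled size <= 20 (method="auto"),
    tie-corrected normal approximation with continuity correction otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    w_a = float(ranks[:n_a].sum())
    u_a = w_a - n_a * (n_a + 1) / 2.0
    N = n_a + n_b

    if method == "auto":
        method = "exact" if N <= EXACT_RANK_SUM_MAX_N else "approx"
    if method == "exact":
        ranks2 = np.round(2 * ranks).astype(np.int64)
        p = _rank_sum_exact_p(ranks2, n_a, int(round(2 * w_a)))
    elif method == "approx":
        mu_u = n_a * n_b / 2.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float((tie_counts**3 - tie_counts).sum()) / (N * (N - 1))
        sigma = np.sqrt(n_a * n_b / 12.0 * ((N + 1) - tie_term))
        if sigma == 0:
            raise DegenerateTestError("zero variance after tie correction")
        z = (u_a - mu_u - 0.5 * np.sign(u_a - mu_u)) / sigma
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    else:
        raise ValueError(f"unknown method {method!r}")

    mu_u = n_a * n_b / 2.0
    direction = "a>b" if u_a > mu_u else ("b>a" if u_a < mu_u else "none")
    return RankSumResult(w_a, u_a, n_a, n_b, p, direction, method)


def paired_inter_distances(
    part_a: PairPartition, part_b: PairPartition
) -> tuple[list[float], list[float], list[tuple[str, str]]]:
    """Align the interspecific distances of two loci on shared sample pairs.

    The pairing key is the unordered sample-pair id; pairs missing (dropped
    out or flagged) at either locus are excluded — this is why the paired n
    differs between locus comparisons.
    """
    da = {tuple(sorted((x, y))): d for x, y, d in part_a.inter_pairs}
    db = {tuple(sorted((x, y))): d for x, y, d in part_b.inter_pairs}
    keys = sorted(da.keys() & db.keys())
    return [da[k] for k in keys], [db[k] for k in keys], keys


# ---------------------------------------------------------------------------
# barcoding gap
# ---------------------------------------------------------------------------


@dataclass
class GapHistogram:
    """Intra vs inter distance histograms on a fine distance scale."""

    bin_width: float
    intra_counts: np.ndarray
    inter_counts: np.ndarray
    zero_fraction_inter_pairs: float
    zero_involved_sample_fraction: float
    sections: list[dict] = field(default_factory=list)  # coarse 0.01-unit summary

    @property
    def n_bins(self) -> int:
        return len(self.intra_counts)

    def bin_edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_width

    def to_rows(self) -> list[dict]:
        return [
            {
                "bin_start": round(i * self.bin_width, 12),
                "intra_count": int(self.intra_counts[i]),
                "inter_count": int(self.inter_counts[i]),
            }
            for i in range(self.n_bins)
        ]


def gap_histogram(part: PairPartition, bin_width: float = 0.001) -> GapHistogram:
    """Histogram intra and inter distances in half-open bins [k*w, (k+1)*w).

    Also reports the fraction of interspecific pairs at distance exactly 0
    and the fraction of all samples involved in at least one zero-distance
    heterospecific pair, plus coarse 0.01-unit section counts.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    intra = part.intra_distances
    inter = part.inter_distances
    all_d = np.concatenate([intra, inter]) if (intra.size or inter.size) else np.array([0.0])
    n_bins = int(np.floor(all_d.max() / bin_width)) + 1 if all_d.size else 1

    def _hist(d: np.ndarray) -> np.ndarray:
        counts = np.zeros(n_bins, dtype=np.int64)
        if d.size:
            idx = np.floor(d / bin_width).astype(int)
            idx = np.minimum(idx, n_bins - 1)  # guard float edge at the max
            np.add.at(counts, idx, 1)
        return counts

    intra_counts = _hist(intra)
    inter_counts = _hist(inter)

    zero_pairs = [(a, b) for a, b, d in part.inter_pairs if d == 0.0]
    zero_frac = len(zero_pairs) / len(part.inter_pairs) if part.inter_pairs else 0.0
    involved = {s for pair in zero_pairs for s in pair}
    involved_frac = len(involved) / part.n_samples if part.n_samples else 0.0

    sections = []
    coarse = 0.01
    n_sections = int(np.floor(all_d.max() / coarse)) + 1
    for k in range(n_sections):
        lo, hi = k * coarse, (k + 1) * coarse
        sections.append(
            {
                "section": f"{lo:.3f}-{hi:.3f}",
                "intra_count": int(((intra >= lo) & (intra < hi)).sum()),
                "inter_count": int(((inter >= lo) & (inter < hi)).sum()),
            }
        )

    return GapHistogram(
        bin_width=bin_width,
        intra_counts=intra_counts,
        inter_counts=inter_counts,
        zero_fraction_inter_pairs=zero_frac,
        zero_involved_sample_fraction=involved_frac,
        sections=sections,
    )
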