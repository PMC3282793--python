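"""Leave-one-out species identification and efficiency reporting.

Two methods are provided, mirroring the two standard barcode-assignment
strategies:

* **nearest distance** — the query is assigned the species of the library
  sample at the smallest genetic distance, provided that distance is below a
  threshold (default 0.01 substitutions/site; a data-driven alternative is
  the 95th percentile of intraspecific distances).
* **best hit** — the query's ungapped sequence is scored against every
  library sequence by local alignment (match +1, mismatch -2, gap open -5,
  gap extend -2) and assigned the species of the top-scoring hit, provided
  the hit's E-value ``E = K*m*n*exp(-lambda*S)`` clears a cutoff (default
  1e-6). lambda and K are the published ungapped Karlin-Altschul constants
  for the +1/-2 nucleotide scheme.

Under leave-one-out, each sample is queried against all remaining samples;
a singleton species has no conspecific reference and can never be called
correctly — singletons stay in every denominator and their count is
reported. Ties at the top (two species at the same minimal distance or
maximal score) yield ``ambiguous``; ambiguous and no_call both count as
failures. Multi-locus combinations use the traffic-light rule: a sample is
identified by a combination as soon as any member locus identifies it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

from .distances import DistanceMatrix
from .divergence import PairPartition
from .io import LocusAlignment, SampleMeta

__all__ = [
    "OUTCOMES",
    "IdentificationCall",
    "IdentificationReport",
    "identify_nearest_distance",
    "identify_best_hit",
    "identify_all_nearest",
    "identify_all_best_hit",
    "traffic_light_combine",
    "efficiency_report",
    "intraspecific_threshold",
    "KARLIN_ALTSCHUL_LAMBDA",
    "KARLIN_ALTSCHUL_K",
]

logger = logging.getLogger(__name__)

OUTCOMES = ("correct", "incorrect", "ambiguous", "no_call")

# ungapped Karlin-Altschul parameters for nucleotide scoring +1/-2
KARLIN_ALTSCHUL_LAMBDA = 1.33
KARLIN_ALTSCHUL_K = 0.621

DEFAULT_DISTANCE_THRESHOLD = 0.01
DEFAULT_EVALUE_CUTOFF = 1e-6


@dataclass(frozen=True)
class IdentificationCall:
    sample_id: str
    true_species: str
    locus: str
    method: str  # "nearest_distance" or "best_hit"
    outcome: str
    best_match_species: str = ""
    score_or_distance: float = float("nan")
    threshold_used: float = float("nan")


def identify_nearest_distance(
    dm: DistanceMatrix,
    query: str,
    threshold: float = DEFAULT_DISTANCE_THRESHOLD,
) -> IdentificationCall:
    """Call one query against the leave-one-out library of ``dm``.

    The call is ``no_call`` when the minimum distance is >= threshold or no
    library distance is defined; ``ambiguous`` when the minimum is attained
    by more than one species.
    """
    qi = dm.index_of(query)
    true_species = dm.species[qi]
    row = dm.values[qi].copy()
    row[qi] = np.nan
    defined = np.isfinite(row)
    base = dict(
        sample_id=query,
        true_species=true_species,
        locus=dm.locus,
        method="nearest_distance",
        threshold_used=threshold,
    )
    if not defined.any():
        logger.warning("%s: query %s has no defined library distances", dm.locus, query)
        return IdentificationCall(outcome="no_call", **base)
    dmin = float(np.nanmin(row))
    if dmin >= threshold:
        return IdentificationCall(outcome="no_call", score_or_distance=dmin, **base)
    hits = {dm.species[j] for j in np.flatnonzero(defined & (row == dmin))}
    if len(hits) > 1:
        return IdentificationCall(
            outcome="ambiguous", score_or_distance=dmin,
            best_match_species=";".join(sorted(hits)), **base,
        )
    match = next(iter(hits))
    outcome = "correct" if match == true_species else "incorrect"
    return IdentificationCall(
        outcome=outcome, best_match_species=match, score_or_distance=dmin, **base
    )


def identify_all_nearest(
    dm: DistanceMatrix, threshold: float = DEFAULT_DISTANCE_THRESHOLD
) -> list[IdentificationCall]:
    """Leave-one-out nearest-distance calls for every sample in ``dm``."""
    return [identify_nearest_distance(dm, sid, threshold) for sid in dm.labels]


def _make_aligner(
    match: float, mismatch: float, gap_open: float, gap_extend: float
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _evalue(score: float, m: int, n_db: int) -> float:
    log_e = (
        np.log(KARLIN_ALTSCHUL_K)
        + np.log(m)
        + np.log(n_db)
        - KARLIN_ALTSCHUL_LAMBDA * score
    )
    # underflow to 0.0 is fine — far below any cutoff
    return float(np.exp(log_e))


def _best_hit_call(
    query: str,
    true_species: str,
    locus: str,
    scores: Mapping[str, float],
    library_species: Mapping[str, str],
    m: int,
    n_db: int,
    evalue_cutoff: float,
) -> IdentificationCall:
    base = dict(
        sample_id=query,
        true_species=true_species,
        locus=locus,
        method="best_hit",
        threshold_used=evalue_cutoff,
    )
    if not scores:
        return IdentificationCall(outcome="no_call", **base)
    best = max(scores.values())
    evalue = _evalue(best, m, n_db)
    if evalue > evalue_cutoff:
        return IdentificationCall(outcome="no_call", score_or_distance=best, **base)
    top_species = {library_species[sid] for sid, s in scores.items() if s == best}
    if len(top_species) > 1:
        return IdentificationCall(
            outcome="ambiguous", score_or_distance=best,
            best_match_species=";".join(sorted(top_species)), **base,
        )
    match = next(iter(top_species))
    outcome = "correct" if match == true_species else "incorrect"
    return IdentificationCall(
        outcome=outcome, best_match_species=match, score_or_distance=best, **base
    )


def identify_best_hit(
    aln: LocusAlignment,
    query: str,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> IdentificationCall:
    """Best-hit call for one query against the leave-one-out library."""
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    qseq = aln.sequence_of(query).replace("-", "")
    true_species = aln.meta_of(query).species
    scores: dict[str, float] = {}
    library_species: dict[str, str] = {}
    n_db = 0
    for meta, seq in zip(aln.samples, aln.sequences):
        if meta.sample_id == query:
            continue
        ungapped = seq.replace("-", "")
        if not ungapped:
            continue
        n_db += len(ungapped)
        library_species[meta.sample_id] = meta.species
        scores[meta.sample_id] = float(aligner.score(qseq, ungapped)) if qseq else 0.0
    return _best_hit_call(
        query, true_species, aln.locus, scores, library_species,
        max(len(qseq), 1), max(n_db, 1), evalue_cutoff,
    )


def identify_all_best_hit(
    aln: LocusAlignment,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> list[IdentificationCall]:
    """Leave-one-out best-hit calls for every sample.

    Local-alignment scores are symmetric under this scoring scheme, so the
    all-pairs score matrix is computed once (upper triangle) and reused for
    every query's library.
    """
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    ids = aln.sample_ids
    species = aln.species_labels
    ungapped = [s.replace("-", "") for s in aln.sequences]
    n = len(ids)
    score_mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if ungapped[i] and ungapped[j]:
                score_mat[i, j] = score_mat[j, i] = float(
                    aligner.score(ungapped[i], ungapped[j])
                )
    calls = []
    for i in range(n):
        scores = {
            ids[j]: score_mat[i, j] for j in range(n) if j != i and ungapped[j]
        }
        lib_species = {ids[j]: species[j] for j in range(n) if j != i}
        n_db = sum(len(ungapped[j]) for j in range(n) if j != i)
        calls.append(
            _best_hit_call(
                ids[i], species[i], aln.locus, scores, lib_species,
                max(len(ungapped[i]), 1), max(n_db, 1), evalue_cutoff,
            )
        )
    return calls


def traffic_light_combine(
    calls_by_locus: Mapping[str, Sequence[IdentificationCall]],
    loci: Sequence[str],
) -> list[IdentificationCall]:
    """Combine per-locus calls under the any-marker-identifies rule.

    Precedence: any ``correct`` -> correct; else any ``incorrect`` ->
    incorrect; else any ``ambiguous`` -> ambiguous; else no_call. Samples
    absent from every member locus are ineligible and omitted.
    """
    per_sample: dict[str, list[IdentificationCall]] = {}
    order: list[str] = []
    for locus in loci:
        for call in calls_by_locus.get(locus, []):
            if call.sample_id not in per_sample:
                per_sample[call.sample_id] = []
                order.append(call.sample_id)
            per_sample[call.sample_id].append(call)
    label = "+".join(loci)
    combined = []
    for sid in order:
        calls = per_sample[sid]
        outcomes = [c.outcome for c in calls]
        for outcome in ("correct", "incorrect", "ambiguous", "no_call"):
            if outcome in outcomes:
                winner = calls[outcomes.index(outcome)]
                break
        combined.append(
            IdentificationCall(
                sample_id=sid,
                true_species=calls[0].true_species,
                locus=label,
                method=calls[0].method,
                outcome=winner.outcome,
                best_match_species=winner.best_match_species,
                score_or_distance=winner.score_or_distance,
                threshold_used=winner.threshold_used,
            )
        )
    return combined


@dataclass
class IdentificationReport:
    """Sample- and species-level identification efficiency for one locus/method."""

    locus: str
    method: str
    sample_efficiency: float
    species_efficiency: float
    n_samples: int            # denominator: all eligible samples
    n_correct_samples: int
    n_species: int            # denominator: all species among eligible samples
    n_correct_species: int    # species with ALL samples called correctly
    n_singleton_species: int
    per_species: dict[str, str]  # species -> "correct" | "failed"


def efficiency_report(
    calls: Sequence[IdentificationCall],
    meta: Sequence[SampleMeta],
    locus: str = "",
    method: str = "",
) -> IdentificationReport:
    """Efficiencies over the eligible population ``meta``.

    A sample in ``meta`` without a call (e.g. amplification dropout) counts
    as a failure; a species succeeds only if every one of its samples is
    called correctly. Singleton species remain in both denominators.
    """
    call_of = {c.sample_id: c for c in calls}
    by_species: dict[str, list[SampleMeta]] = {}
    for m in meta:
        by_species.setdefault(m.species, []).append(m)

    n_correct = sum(
        1 for m in meta
        if m.sample_id in call_of and call_of[m.sample_id].outcome == "correct"
    )
    per_species = {}
    for sp, members in sorted(by_species.items()):
        ok = all(
            m.sample_id in call_of and call_of[m.sample_id].outcome == "correct"
            for m in members
        )
        per_species[sp] = "correct" if ok else "failed"
    n_correct_species = sum(1 for v in per_species.values() if v == "correct")
    n_singletons = sum(1 for members in by_species.values() if len(members) == 1)

    return IdentificationReport(
        locus=locus or (calls[0].locus if calls else ""),
        method=method or (calls[0].method if calls else ""),
        sample_efficiency=n_correct / len(meta) if meta else 0.0,
        species_efficiency=n_correct_species / len(by_species) if by_species else 0.0,
        n_samples=len(meta),
        n_correct_samples=n_correct,
        n_species=len(by_species),
        n_correct_species=n_correct_species,
        n_singleton_species=n_singletons,
        per_species=per_species,
    )


def intraspecific_threshold(part: PairPartition, percentile: float = 95.0) -> float:
    """Data-driven nearest-distance threshold: a percentile of intra distances."""
    intra = part.intra_distances
    if intra.size == 0:
        raise ValueError("no intraspecific distances to derive a threshold from")
    return float(np.percentile(intra, percentile))
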