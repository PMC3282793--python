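"""Alignment summary statistics: conserved, variable and parsimony-informative sites.

Column classification considers only unambiguous bases {A,C,G,T}; gap
characters and IUPAC ambiguity codes are ignored within a column. A column
with fewer than two unambiguous bases carries no comparison information and
is counted as excluded, so the partition

    conserved + variable + excluded == alignment_length
    parsimony_informative + singleton == variable

always holds exactly. Sites containing gaps are not excluded wholesale —
only sites with <2 usable bases — consistent with the pairwise-deletion
philosophy used for distances.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .io import LocusAlignment

__all__ = ["AlignmentStats", "compute_alignment_stats", "stats_table", "write_stats_table"]

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class AlignmentStats:
    """Per-locus site-class counts (a one-row alignment summary)."""

    locus: str
    n_sequences: int
    min_seq_len: int          # ungapped
    max_seq_len: int          # ungapped
    alignment_length: int
    conserved_sites: int
    variable_sites: int
    parsim_informative_sites: int
    singleton_sites: int
    excluded_sites: int


def _encode(aln: LocusAlignment) -> np.ndarray:
    """Alignment as a (n, L) byte matrix."""
    return np.frombuffer(
        "".join(aln.sequences).encode("ascii"), dtype="S1"
    ).reshape(aln.n_members, aln.alignment_length)


def compute_alignment_stats(aln: LocusAlignment) -> AlignmentStats:
    """Classify every column of ``aln`` and count the site classes.

    Per column: collect the unambiguous bases; <2 of them → excluded; all
    identical → conserved; otherwise variable, and parsimony-informative iff
    at least two distinct bases each occur in at least two sequences
    (else a singleton site).
    """
    if aln.n_members < 2:
        raise InsufficientDataError(
            f"{aln.locus}: need >=2 sequences, have {aln.n_members}"
        )
    mat = _encode(aln)
    counts = np.stack([(mat == b.encode()).sum(axis=0) for b in _BASES])  # (4, L)
    usable = counts.sum(axis=0)
    distinct = (counts > 0).sum(axis=0)
    shared = (counts >= 2).sum(axis=0)  # bases present in >=2 sequences

    excluded = usable < 2
    conserved = ~excluded & (distinct == 1)
    variable = ~excluded & (distinct >= 2)
    informative = variable & (shared >= 2)
    singleton = variable & ~informative

    ungapped = [len(s.replace("-", "")) for s in aln.sequences]
    return AlignmentStats(
        locus=aln.locus,
        n_sequences=aln.n_members,
        min_seq_len=min(ungapped),
        max_seq_len=max(ungapped),
        alignment_length=aln.alignment_length,
        conserved_sites=int(conserved.sum()),
        variable_sites=int(variable.sum()),
        parsim_informative_sites=int(informative.sum()),
        singleton_sites=int(singleton.sum()),
        excluded_sites=int(excluded.sum()),
    )


def stats_table(stats: Sequence[AlignmentStats]) -> pd.DataFrame:
    """One row per locus, columns as the AlignmentStats fields."""
    return pd.DataFrame([asdict(s) for s in stats])


def write_stats_table(stats: Sequence[AlignmentStats], path: str | Path) -> None:
    stats_table(stats).to_csv(path, sep="\t", index=False)
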