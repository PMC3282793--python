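"""Pairwise genetic distances under pairwise deletion: K2P and p-distance.

The Kimura 2-parameter distance separates transitions (A<->G, C<->T) from
transversions:

    d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q)

with P and Q the per-pair transition and transversion proportions over the
sites where both sequences carry an unambiguous base (pairwise deletion:
gaps and IUPAC ambiguities are skipped per pair, never per column). The
p-distance is the raw mismatch proportion P + Q over the same sites.

Saturated pairs (log argument <= 0) and pairs with zero comparable sites are
flagged as missing (NaN) in :func:`distance_matrix` and excluded, with a
logged count, from every downstream summary; they are never clamped to a
ceiling value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, SaturationError, UndefinedDistanceError
from .io import LocusAlignment

__all__ = ["MODELS", "DistanceMatrix", "pairwise_distance", "distance_matrix"]

logger = logging.getLogger(__name__)

MODELS = ("k2p", "p-distance")

# byte codes: A=0 C=1 G=2 T=3, anything else (gap/ambiguity) = 255
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _pq(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(transitions, transversions, comparable sites) for two coded sequences."""
    ok = (a != 255) & (b != 255)
    n = int(ok.sum())
    diff = ok & (a != b)
    # A=0,G=2 are even; C=1,T=3 are odd: a transition keeps parity
    transitions = int((diff & ((a & 1) == (b & 1))).sum())
    transversions = int(diff.sum()) - transitions
    return transitions, transversions, n


def _k2p(P: float, Q: float) -> float:
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0.0 or arg2 <= 0.0:
        raise SaturationError(
            f"K2P undefined: P={P:.4g}, Q={Q:.4g} (log argument <= 0)", P=P, Q=Q
        )
    return -0.5 * np.log(arg1) - 0.25 * np.log(arg2)


def pairwise_distance(
    seq_a: str, seq_b: str, model: str = "k2p"
) -> tuple[float, int]:
    """Distance between two aligned sequences and the comparable-site count.

    Raises :class:`UndefinedDistanceError` when no site is comparable and
    :class:`SaturationError` when the K2P logarithm is undefined.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal (aligned) length")
    a, b = _encode(seq_a.upper()), _encode(seq_b.upper())
    ts, tv, n = _pq(a, b)
    if n == 0:
        raise UndefinedDistanceError("zero comparable sites between the pair")
    P, Q = ts / n, tv / n
    if model == "p-distance":
        return P + Q, n
    return _k2p(P, Q), n


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with sample and species labels.

    ``values`` holds NaN for flagged-missing pairs (saturation or zero
    comparable sites); ``comparable_sites[i, j]`` is the number of sites the
    pair was scored on.
    """

    labels: list[str]
    species: list[str]
    model: str
    values: np.ndarray
    comparable_sites: np.ndarray
    n_flagged_missing: int = 0
    locus: str = ""
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n(self) -> int:
        return len(self.labels)

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.values[self._index[id_a], self._index[id_b]])

    def index_of(self, sample_id: str) -> int:
        return self._index[sample_id]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path: str | Path) -> None:
        """Square-matrix TSV, labels as first row and column."""
        df = self.to_dataframe().round(10)
        df.to_csv(path, sep="\t", index_label="sample_id")

    def write_phylip(self, path: str | Path) -> None:
        """Square PHYLIP distance format."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for lab, row in zip(self.labels, self.values):
                vals = " ".join(f"{v:.8f}" if np.isfinite(v) else "nan" for v in row)
                fh.write(f"{lab:<12s}{vals}\n")


def distance_matrix(aln: LocusAlignment, model: str = "k2p") -> DistanceMatrix:
    """All pairwise distances for an alignment.

    Saturated/undefined pairs become NaN and are counted in
    ``n_flagged_missing`` (also logged at WARNING level).
    """
    if aln.n_members < 2:
        raise InsufficientDataError(
            f"{aln.locus}: need >=2 members for a distance matrix"
        )
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    n = aln.n_members
    coded = np.stack([_encode(s) for s in aln.sequences])
    values = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=np.int64)
    flagged = 0
    for i in range(n):
        comp[i, i] = int((coded[i] != 255).sum())
        for j in range(i + 1, n):
            ts, tv, c = _pq(coded[i], coded[j])
            comp[i, j] = comp[j, i] = c
            if c == 0:
                values[i, j] = values[j, i] = np.nan
                flagged += 1
                continue
            P, Q = ts / c, tv / c
            if model == "p-distance":
                d = P + Q
            else:
                try:
                    d = _k2p(P, Q)
                except SaturationError:
                    values[i, j] = values[j, i] = np.nan
                    flagged += 1
                    continue
            values[i, j] = values[j, i] = d
    if flagged:
        logger.warning(
            "%s: %d pair(s) flagged missing (saturation or no comparable sites)",
            aln.locus or "alignment", flagged,
        )
    return DistanceMatrix(
        labels=aln.sample_ids,
        species=aln.species_labels,
        model=model,
        values=values,
        comparable_sites=comp,
        n_flagged_missing=flagged,
        locus=aln.locus,
    )
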