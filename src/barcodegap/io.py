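"""Aligned-FASTA and sample-metadata I/O, per-locus datasets, concatenation.

The universal input for every downstream computation is a
:class:`LocusAlignment`: species-labelled, pre-aligned sequences for one
locus. Alignment itself is upstream of this package — inputs are assumed to
be already aligned (gaps as ``-``). Sequences are normalized to uppercase
and RNA ``U`` is mapped to ``T`` on read; IUPAC ambiguity codes are
preserved and handled per-operation downstream.

Metadata is a UTF-8 tab-separated table whose header starts with
``sample_id<TAB>species``; extra columns (voucher, locality, ...) are kept
as per-sample annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentShapeError,
    DuplicateSampleError,
    InsufficientOverlapError,
    MetadataError,
)

__all__ = [
    "SampleMeta",
    "LocusAlignment",
    "MultiLocusDataset",
    "read_metadata",
    "write_metadata",
    "read_locus_alignment",
    "write_locus_alignment",
    "concatenate_loci",
]


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one sampled individual: unique id plus its species label."""

    sample_id: str
    species: str
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.sample_id:
            raise MetadataError("sample_id must be non-empty")
        if not self.species:
            raise MetadataError(f"species label for {self.sample_id!r} must be non-empty")


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


class LocusAlignment:
    """Species-labelled aligned sequences for one locus.

    Parameters
    ----------
    locus : str
        Locus name (e.g. ``"matK"``).
    samples : sequence of SampleMeta
        One entry per sequence, in alignment order.
    sequences : sequence of str
        Aligned sequences over ``{A,C,G,T, IUPAC ambiguity codes, -}``;
        all the same length.
    """

    def __init__(self, locus: str, samples: Sequence[SampleMeta], sequences: Sequence[str]):
        if len(samples) != len(sequences):
            raise AlignmentShapeError(
                f"{locus}: {len(samples)} metadata entries but {len(sequences)} sequences"
            )
        sequences = [_normalize(s) for s in sequences]
        if sequences:
            length = len(sequences[0])
            for meta, seq in zip(samples, sequences):
                if len(seq) != length:
                    raise AlignmentShapeError(
                        f"{locus}: record {meta.sample_id!r} has length {len(seq)}, "
                        f"expected {length}"
                    )
        else:
            length = 0
        seen: set[str] = set()
        for meta in samples:
            if meta.sample_id in seen:
                raise DuplicateSampleError(
                    f"{locus}: duplicate sample_id {meta.sample_id!r}"
                )
            seen.add(meta.sample_id)
        self.locus = locus
        self.samples = list(samples)
        self.sequences = list(sequences)
        self.alignment_length = length

    @property
    def n_members(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.samples]

    @property
    def species_labels(self) -> list[str]:
        return [m.species for m in self.samples]

    def sequence_of(self, sample_id: str) -> str:
        for meta, seq in zip(self.samples, self.sequences):
            if meta.sample_id == sample_id:
                return seq
        raise KeyError(sample_id)

    def meta_of(self, sample_id: str) -> SampleMeta:
        for meta in self.samples:
            if meta.sample_id == sample_id:
                return meta
        raise KeyError(sample_id)

    def subset(self, sample_ids: Iterable[str]) -> "LocusAlignment":
        """Restrict to the given sample ids, preserving their given order."""
        wanted = list(sample_ids)
        by_id = {m.sample_id: (m, s) for m, s in zip(self.samples, self.sequences)}
        pairs = [by_id[i] for i in wanted]
        return LocusAlignment(self.locus, [p[0] for p in pairs], [p[1] for p in pairs])

    def __len__(self) -> int:
        return self.n_members

    def __repr__(self) -> str:
        return (
            f"LocusAlignment({self.locus!r}, {self.n_members} members x "
            f"{self.alignment_length} columns)"
        )


class MultiLocusDataset:
    """A set of per-locus alignments over one sample collection.

    A sample may be absent from some loci (amplification dropout); its species
    label must be identical wherever it does appear.
    """

    def __init__(self, loci: Sequence[LocusAlignment]):
        species_of: dict[str, str] = {}
        for aln in loci:
            for meta in aln.samples:
                prev = species_of.get(meta.sample_id)
                if prev is not None and prev != meta.species:
                    raise MetadataError(
                        f"sample {meta.sample_id!r} is {prev!r} in one locus "
                        f"but {meta.species!r} in {aln.locus!r}"
                    )
                species_of[meta.sample_id] = meta.species
        self.loci = list(loci)
        self.species_of = species_of

    @property
    def locus_names(self) -> list[str]:
        return [aln.locus for aln in self.loci]

    def get_locus(self, name: str) -> LocusAlignment:
        for aln in self.loci:
            if aln.locus == name:
                return aln
        raise KeyError(f"no locus named {name!r}")

    def presence(self) -> dict[str, set[str]]:
        """Map sample_id -> set of locus names where the sample has a sequence."""
        out: dict[str, set[str]] = {}
        for aln in self.loci:
            for sid in aln.sample_ids:
                out.setdefault(sid, set()).add(aln.locus)
        return out

    def all_samples(self) -> list[SampleMeta]:
        """Every distinct sample across loci, first-seen order."""
        seen: dict[str, SampleMeta] = {}
        for aln in self.loci:
            for meta in aln.samples:
                seen.setdefault(meta.sample_id, meta)
        return list(seen.values())


def read_metadata(meta_path: str | Path) -> dict[str, SampleMeta]:
    """Read the tab-separated sample metadata table.

    Returns a mapping sample_id -> :class:`SampleMeta`. Columns beyond
    ``sample_id`` and ``species`` go into ``extra``.
    """
    df = pd.read_csv(meta_path, sep="\t", dtype=str).fillna("")
    for col in ("sample_id", "species"):
        if col not in df.columns:
            raise MetadataError(f"{meta_path}: missing required column {col!r}")
    extra_cols = [c for c in df.columns if c not in ("sample_id", "species")]
    out: dict[str, SampleMeta] = {}
    for row in df.itertuples(index=False):
        rec = row._asdict()
        sid = rec["sample_id"]
        if sid in out:
            raise DuplicateSampleError(f"{meta_path}: duplicate sample_id {sid!r}")
        out[sid] = SampleMeta(sid, rec["species"], {c: rec[c] for c in extra_cols if rec[c]})
    return out


def write_metadata(samples: Sequence[SampleMeta], meta_path: str | Path) -> None:
    extra_cols: list[str] = []
    for m in samples:
        for k in m.extra:
            if k not in extra_cols:
                extra_cols.append(k)
    rows = [
        {"sample_id": m.sample_id, "species": m.species, **{k: m.extra.get(k, "") for k in extra_cols}}
        for m in samples
    ]
    pd.DataFrame(rows, columns=["sample_id", "species", *extra_cols]).to_csv(
        meta_path, sep="\t", index=False
    )


def read_locus_alignment(
    fasta_path: str | Path, meta_path: str | Path, locus: str
) -> LocusAlignment:
    """Read one aligned FASTA plus metadata into a :class:`LocusAlignment`.

    Members keep the FASTA order; every record ID must have a metadata row.
    Raises :class:`AlignmentShapeError` on ragged input (naming the offending
    record), :class:`MetadataError` on a missing metadata row and
    :class:`DuplicateSampleError` on repeated ids.
    """
    meta = read_metadata(meta_path)
    samples: list[SampleMeta] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in meta:
            raise MetadataError(
                f"{fasta_path}: record {rec.id!r} has no row in {meta_path}"
            )
        samples.append(meta[rec.id])
        seqs.append(str(rec.seq))
    return LocusAlignment(locus, samples, seqs)


def write_locus_alignment(
    aln: LocusAlignment, fasta_path: str | Path, meta_path: str | Path | None = None
) -> None:
    """Write unwrapped aligned FASTA (and optionally the metadata TSV)."""
    records = [
        SeqRecord(Seq(seq), id=meta.sample_id, description="")
        for meta, seq in zip(aln.samples, aln.sequences)
    ]
    with open(fasta_path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(records)
    if meta_path is not None:
        write_metadata(aln.samples, meta_path)


def concatenate_loci(dataset: MultiLocusDataset, loci: Sequence[str]) -> LocusAlignment:
    """Concatenate named loci into one supermatrix alignment.

    Only samples present in *all* named loci are kept (intersection
    semantics); sequences are joined in the given locus order and the
    combined locus is named by joining the names with ``"+"``.
    """
    if len(loci) < 2:
        raise ValueError("concatenation needs at least two locus names")
    alns = [dataset.get_locus(name) for name in loci]
    shared = [sid for sid in alns[0].sample_ids if all(sid in a.sample_ids for a in alns[1:])]
    if len(shared) < 2:
        raise InsufficientOverlapError(
            f"only {len(shared)} sample(s) shared across {'+'.join(loci)}"
        )
    id_sets = [{m.sample_id: s for m, s in zip(a.samples, a.sequences)} for a in alns]
    samples = [alns[0].meta_of(sid) for sid in shared]
    sequences = ["".join(ids[sid] for ids in id_sets) for sid in shared]
    return LocusAlignment("+".join(loci), samples, sequences)
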