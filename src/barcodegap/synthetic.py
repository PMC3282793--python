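"""Seeded generator of species-structured multi-locus alignment datasets.

The generator emulates a genus-level barcode study: a star phylogeny of
species, each sample evolved from its species ancestor with expected
divergence ``expected_intra/2`` per lineage (so conspecific pairs diverge
by about ``expected_intra``), and each species ancestor evolved from a
common root by ``(expected_inter - expected_intra)/2`` so that the expected
divergence between *samples* of different species is ``expected_inter`` —
the calibration targets are the observable distance summaries (all-intra
and all-inter means), not ancestral quantities. Setting
``expected_intra == expected_inter`` therefore collapses the species
structure entirely (zero-length internal branches), the limiting case where
identification must fail. Substitutions follow a two-rate
process: per site the number of events is Poisson with mean equal to the
branch length, and each event is a transition with probability
``kappa/(kappa+2)`` (Kimura's two-parameter scheme). Calibration is in
expected substitutions per site, not time/rate pairs, because the targets
being emulated are distances.

Optional features mirror common plastid-marker pathologies: a large indel
block flanked by AT-rich repeat motifs in a subset of species (non-coding
spacers), and independent per-sample-per-locus Bernoulli dropout
(amplification failure). Ambiguity codes are not generated.

All randomness derives from the single config seed: the same config is
guaranteed to reproduce byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import BoundsError, ValidationError
from .io import LocusAlignment, MultiLocusDataset, SampleMeta, write_locus_alignment, write_metadata

__all__ = [
    "IndelSpec",
    "LocusSpec",
    "SynthConfig",
    "SyntheticTruth",
    "generate_dataset",
    "inject_indel",
    "dioscorea_like_profile",
    "write_dataset",
]

_ALPHABET = np.array(list("ACGT"))


@dataclass(frozen=True)
class IndelSpec:
    """A large insertion present in a fraction of species, AT-rich flanked.

    Species without the insert are gap-padded over the block so the
    alignment stays rectangular.
    """

    insert_length: int
    position: int
    flank_repeat: str = "ATATAT"
    fraction_with_insert: float = 0.1

    def validate(self, locus_length: int) -> None:
        if not (0 <= self.position <= locus_length):
            raise ValidationError(
                f"indel position {self.position} outside locus of length {locus_length}"
            )
        if self.insert_length <= 0:
            raise ValidationError("insert_length must be positive")
        if not (0.0 <= self.fraction_with_insert <= 1.0):
            raise ValidationError("fraction_with_insert must be in [0, 1]")


@dataclass(frozen=True)
class LocusSpec:
    name: str
    length: int
    expected_inter: float
    expected_intra: float
    kappa: float = 2.0
    dropout_prob: float = 0.0
    indel: IndelSpec | None = None

    def validate(self) -> None:
        if self.length <= 0:
            raise ValidationError(f"{self.name}: length must be positive")
        if self.expected_intra < 0 or self.expected_inter < self.expected_intra:
            raise ValidationError(
                f"{self.name}: need expected_inter >= expected_intra >= 0"
            )
        if self.kappa <= 0:
            raise ValidationError(f"{self.name}: kappa must be positive")
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ValidationError(f"{self.name}: dropout_prob must be in [0, 1]")
        if self.indel is not None:
            self.indel.validate(self.length)


@dataclass(frozen=True)
class SynthConfig:
    """Full generator configuration; all randomness flows from ``seed``."""

    n_species: int
    samples_per_species: int | Sequence[int]
    loci: Sequence[LocusSpec]
    seed: int

    def counts(self) -> list[int]:
        if isinstance(self.samples_per_species, int):
            return [self.samples_per_species] * self.n_species
        return list(self.samples_per_species)

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValidationError("n_species must be >= 1")
        counts = self.counts()
        if len(counts) != self.n_species:
            raise ValidationError(
                f"samples_per_species has {len(counts)} entries for "
                f"{self.n_species} species"
            )
        if any(c < 1 for c in counts):
            raise ValidationError("every species needs >= 1 sample")
        if not self.loci:
            raise ValidationError("at least one locus is required")
        names = [loc.name for loc in self.loci]
        if len(set(names)) != len(names):
            raise ValidationError("locus names must be unique")
        for loc in self.loci:
            loc.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        loci = []
        for loc in d["loci"]:
            loc = dict(loc)
            if loc.get("indel"):
                loc["indel"] = IndelSpec(**loc["indel"])
            else:
                loc["indel"] = None
            loci.append(LocusSpec(**loc))
        return cls(
            n_species=d["n_species"],
            samples_per_species=d["samples_per_species"],
            loci=loci,
            seed=d["seed"],
        )


@dataclass
class SyntheticTruth:
    """Ground truth emitted with every generated dataset."""

    config: SynthConfig
    species_ancestors: dict[str, dict[str, str]]      # locus -> species -> seq
    sample_sequences: dict[str, dict[str, str]]       # locus -> sample -> seq (pre-dropout)
    species_of: dict[str, str]
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (locus, sample)
    indel_species: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "species_of": self.species_of,
            "dropped": [list(t) for t in self.dropped],
            "indel_species": self.indel_species,
            "species_ancestors": self.species_ancestors,
        }


def _transition_prob(kappa: float) -> float:
    # one transition channel (rate kappa) vs two transversion channels (rate 1 each)
    return kappa / (kappa + 2.0)


def _mutate(codes: np.ndarray, branch: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve a coded sequence by expected ``branch`` substitutions/site."""
    out = codes.copy()
    if branch <= 0:
        return out
    n_events = rng.poisson(branch, codes.size)
    p_ts = _transition_prob(kappa)
    for idx in np.flatnonzero(n_events):
        c = int(out[idx])
        for _ in range(int(n_events[idx])):
            if rng.random() < p_ts:
                c ^= 2          # A<->G, C<->T (codes 0<->2, 1<->3)
            else:
                c ^= 1 if rng.random() < 0.5 else 3
        out[idx] = c
    return out


def _decode(codes: np.ndarray) -> str:
    return "".join(_ALPHABET[codes])


def _at_rich_sequence(length: int, rng: np.random.Generator) -> str:
    # 80% A/T, matching the AT-repeat-flanked spacer inserts being emulated
    return "".join(rng.choice(list("ACGT"), size=length, p=[0.4, 0.1, 0.1, 0.4]))


def inject_indel(
    aln: LocusAlignment,
    spec: IndelSpec,
    species_subset: Sequence[str],
    rng: np.random.Generator | None = None,
) -> LocusAlignment:
    """Insert ``flank + insert + flank`` into the chosen species at ``position``.

    All other sequences receive gap characters of the same width, keeping the
    alignment rectangular. The new alignment length is the old one plus
    ``insert_length + 2*len(flank_repeat)``.
    """
    if not (0 <= spec.position <= aln.alignment_length):
        raise BoundsError(
            f"indel position {spec.position} outside alignment of length "
            f"{aln.alignment_length}"
        )
    if rng is None:
        rng = np.random.default_rng(0)
    chosen = set(species_subset)
    insert = spec.flank_repeat + _at_rich_sequence(spec.insert_length, rng) + spec.flank_repeat
    gap_block = "-" * len(insert)
    pos = spec.position
    sequences = [
        seq[:pos] + (insert if meta.species in chosen else gap_block) + seq[pos:]
        for meta, seq in zip(aln.samples, aln.sequences)
    ]
    return LocusAlignment(aln.locus, aln.samples, sequences)


def generate_dataset(config: SynthConfig) -> tuple[MultiLocusDataset, SyntheticTruth]:
    """Generate a multi-locus dataset plus its ground truth, reproducibly."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = config.counts()
    width = len(str(config.n_species))
    species_names = [f"species_{i + 1:0{width}d}" for i in range(config.n_species)]
    sample_meta: list[SampleMeta] = []
    for sp, c in zip(species_names, counts):
        for k in range(c):
            sample_meta.append(SampleMeta(f"{sp}_s{k + 1}", sp))
    species_of = {m.sample_id: m.species for m in sample_meta}

    loci_alignments: list[LocusAlignment] = []
    truth = SyntheticTruth(
        config=config,
        species_ancestors={},
        sample_sequences={},
        species_of=species_of,
        dropped=[],
        indel_species={},
    )

    for loc in config.loci:
        root = rng.integers(0, 4, loc.length, dtype=np.int64)
        species_branch = (loc.expected_inter - loc.expected_intra) / 2.0
        ancestors = {
            sp: _mutate(root, species_branch, loc.kappa, rng)
            for sp in species_names
        }
        sequences: list[str] = []
        for meta in sample_meta:
            codes = _mutate(
                ancestors[meta.species], loc.expected_intra / 2.0, loc.kappa, rng
            )
            sequences.append(_decode(codes))
        aln = LocusAlignment(loc.name, sample_meta, sequences)

        if loc.indel is not None and loc.indel.fraction_with_insert > 0:
            n_with = int(round(loc.indel.fraction_with_insert * config.n_species))
            n_with = max(1, n_with)
            chosen = sorted(
                str(sp) for sp in
                rng.choice(species_names, size=min(n_with, config.n_species), replace=False)
            )
            aln = inject_indel(aln, loc.indel, chosen, rng)
            truth.indel_species[loc.name] = list(chosen)

        truth.species_ancestors[loc.name] = {
            sp: _decode(codes) for sp, codes in ancestors.items()
        }
        truth.sample_sequences[loc.name] = dict(zip(aln.sample_ids, aln.sequences))

        keep_mask = rng.random(len(sample_meta)) >= loc.dropout_prob
        kept_ids = [m.sample_id for m, keep in zip(sample_meta, keep_mask) if keep]
        truth.dropped.extend(
            (loc.name, m.sample_id) for m, keep in zip(sample_meta, keep_mask) if not keep
        )
        loci_alignments.append(aln.subset(kept_ids))

    return MultiLocusDataset(loci_alignments), truth


def dioscorea_like_profile(seed: int) -> SynthConfig:
    """Default emulation profile: a yam-like genus-level barcode study.

    38 species with 1-8 samples each (148 samples total); three plastid
    loci with lengths, intra/inter divergence levels and per-locus dropout
    rates in the range reported for genus-level plant-barcode surveys; the
    non-coding spacer carries a 234-bp AT-rich-flanked insert at position
    183 in a small fraction of species.
    """
    counts = (
        [1] * 6 + [2] * 4 + [3] * 6 + [4] * 8 + [5] * 6 + [6] * 4 + [7] * 2 + [8] * 2
    )
    assert len(counts) == 38 and sum(counts) == 148
    return SynthConfig(
        n_species=38,
        samples_per_species=counts,
        loci=[
            LocusSpec("matK", 752, expected_inter=0.0295, expected_intra=0.0095,
                      kappa=2.0, dropout_prob=0.298),
            LocusSpec("rbcL", 553, expected_inter=0.0125, expected_intra=0.0019,
                      kappa=2.0, dropout_prob=0.167),
            LocusSpec("psbA-trnH", 300, expected_inter=0.0879, expected_intra=0.0195,
                      kappa=2.0, dropout_prob=0.259,
                      indel=IndelSpec(insert_length=234, position=183,
                                      flank_repeat="ATATAT", fraction_with_insert=0.08)),
        ],
        seed=seed,
    )


def write_dataset(
    dataset: MultiLocusDataset,
    truth: SyntheticTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Emit per-locus aligned FASTA, the metadata TSV and a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    all_meta = dataset.all_samples()
    meta_path = outdir / "samples.tsv"
    write_metadata(all_meta, meta_path)
    paths["metadata"] = meta_path
    for aln in dataset.loci:
        p = outdir / f"{aln.locus}.fasta"
        write_locus_alignment(aln, p)
        paths[aln.locus] = p
    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth.to_json(), fh, indent=2, sort_keys=True)
    paths["truth"] = truth_path
    return paths
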