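import numpy as np
import pytest

from barcodegap import LocusAlignment, MultiLocusDataset, SampleMeta


def make_alignment(locus, rows):
    """rows: list of (sample_id, species, sequence)."""
    return LocusAlignment(
        locus,
        [SampleMeta(sid, sp) for sid, sp, _ in rows],
        [seq for _, _, seq in rows],
    )


@pytest.fixture
def two_species_aln():
    """2 species x 2 samples, well separated, length 20."""
    return make_alignment(
        "toy",
        [
            ("a1", "spA", "ACGTACGTACGTACGTACGT"),
            ("a2", "spA", "ACGTACGTACGTACGTACGA"),
            ("b1", "spB", "TGCATGCATGCAACGTACGT"),
            ("b2", "spB", "TGCATGCATGCAACGTACGA"),
        ],
    )


def random_alignment(rng, n_seq=6, length=50, locus="rand", n_species=3,
                     gap_frac=0.05, ambig_frac=0.03):
    """Random alignment with gaps and ambiguity codes sprinkled in."""
    chars = np.array(list("ACGT"))
    mat = chars[rng.integers(0, 4, (n_seq, length))]
    for sym, frac in (("-", gap_frac), ("N", ambig_frac / 2), ("R", ambig_frac / 2)):
        mask = rng.random((n_seq, length)) < frac
        mat[mask] = sym
    rows = [
        (f"s{i}", f"sp{i % n_species}", "".join(mat[i]))
        for i in range(n_seq)
    ]
    return make_alignment(locus, rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_dataset():
    """Two loci sharing 3 of 4 samples."""
    locA = make_alignment(
        "locA",
        [
            ("a1", "spA", "ACGTACGTAC"),
            ("a2", "spA", "ACGTACGTAT"),
            ("b1", "spB", "TGCATGCATG"),
            ("b2", "spB", "TGCATGCATC"),
        ],
    )
    locB = make_alignment(
        "locB",
        [
            ("a1", "spA", "GGGGGCCC"),
            ("a2", "spA", "GGGGGCCT"),
            ("b1", "spB", "AAAAATTT"),
        ],
    )
    return MultiLocusDataset([locA, locB])
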