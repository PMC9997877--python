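import numpy as np
import pytest

from dftclust import FamilySpec, SequenceRecord, generate_families

#: The worked-example gene and its printed DFT spectra, frozen to the
#: 3-decimal precision they are published at (base order A, T, G, C).
EXAMPLE_GENE = "agcttta"
EXAMPLE_SPECTRA = {
    "A": [2, 1.623 + 0.782j, 0.777 + 0.975j, 0.099 + 0.434j,
          0.099 - 0.434j, 0.777 - 0.975j, 1.623 - 0.782j],
    "T": [3, -2.024 + 0.975j, 0.346 - 0.434j, 0.178 - 0.782j,
          0.178 + 0.782j, 0.346 + 0.434j, -2.024 - 0.975j],
    "G": [1, 0.623 - 0.782j, -0.223 - 0.975j, -0.901 - 0.434j,
          -0.901 + 0.434j, -0.223 + 0.975j, 0.623 + 0.782j],
    "C": [1, -0.223 - 0.975j, -0.901 + 0.434j, 0.623 + 0.782j,
          0.623 - 0.782j, -0.901 - 0.434j, -0.223 + 0.975j],
}


@pytest.fixture
def example_record() -> SequenceRecord:
    from dftclust.seq_io import normalize_residues

    return SequenceRecord("g1", normalize_residues(EXAMPLE_GENE))


@pytest.fixture(scope="session")
def default_families():
    """The default synthetic fixture: 4 families x 6 members, 2% subs."""
    return generate_families(FamilySpec())


@pytest.fixture
def random_records():
    """50 seeded random DNA records of assorted lengths (some with Ns)."""
    rng = np.random.default_rng(42)
    records = []
    for i in range(50):
        n = int(rng.integers(2, 200))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        if i % 5 == 0:  # sprinkle ambiguity
            pos = int(rng.integers(0, n))
            seq = seq[:pos] + "N" + seq[pos + 1 :]
        records.append(SequenceRecord(f"r{i}", seq))
    return records


def write_fasta_text(tmp_path, text, name="in.fa"):
    path = tmp_path / name
    path.write_text(text)
    return path
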