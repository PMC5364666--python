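import random

import pytest

from orthobridge import (Proteome, SequenceRecord, SearchConfig, load_builtin)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def blosum62():
    return load_builtin("BLOSUM62")


@pytest.fixture(scope="session")
def blosum45():
    return load_builtin("BLOSUM45")


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AA20) for _ in range(length))


def mutate(rng: random.Random, seq: str, n_sub: int) -> str:
    """n point substitutions at distinct positions."""
    chars = list(seq)
    for pos in rng.sample(range(len(seq)), min(n_sub, len(seq))):
        chars[pos] = rng.choice(AA20.replace(chars[pos], ""))
    return "".join(chars)


def make_record(rec_id: str, species: str, seq: str) -> SequenceRecord:
    return SequenceRecord(id=rec_id, species=species, residues=seq)


def family_universe(seed: int, species: list, n_decoys: int = 3,
                    length: int = 120, divergence: int = 25):
    """A toy universe: one family (per-species mutated copies of a common
    root) plus random decoys.  Returns ({species: Proteome}, {species: id})."""
    rng = random.Random(seed)
    root = random_protein(rng, length)
    universe, members = {}, {}
    for sp in species:
        fam_id = f"{sp}_fam"
        records = [make_record(fam_id, sp, mutate(rng, root, divergence))]
        for i in range(n_decoys):
            records.append(make_record(f"{sp}_d{i}", sp,
                                       random_protein(rng, length)))
        universe[sp] = Proteome(species=sp, records=records)
        members[sp] = fam_id
    return universe, members


@pytest.fixture(scope="session")
def fungal_config():
    return SearchConfig.fungal()


@pytest.fixture(scope="session")
def relaxed_config():
    return SearchConfig.relaxed()
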