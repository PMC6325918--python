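import numpy as np
import pytest

from reactnorm.pedigree import Pedigree


@pytest.fixture(scope="session")
def diallel_pedigree():
    """Small two-species diallel: 3 EL x 3 JL parents, 2 hybrids per cross."""
    recs = [(f"E{i}", None, None, "EL") for i in range(3)]
    recs += [(f"J{i}", None, None, "JL") for i in range(3)]
    k = 0
    for e in range(3):
        for j in range(3):
            for _ in range(2):
                recs.append((f"H{k}", f"E{e}", f"J{j}", "HL"))
                k += 1
    return Pedigree.from_records(recs)


@pytest.fixture(scope="session")
def nuclear_pedigree():
    """Sire, dam, three full-sib offspring plus a half-sib."""
    return Pedigree.from_records(
        [
            ("s1", None, None, ""),
            ("d1", None, None, ""),
            ("d2", None, None, ""),
            ("o1", "s1", "d1", ""),
            ("o2", "s1", "d1", ""),
            ("o3", "s1", "d1", ""),
            ("h1", "s1", "d2", ""),
        ]
    )


@pytest.fixture()
def rng():
    # function-scoped: the stream is identical regardless of test order
    return np.random.default_rng(20260922)
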