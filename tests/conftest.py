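import numpy as np
import pytest

from tagdge.index import build_index
from tagdge.synthetic import SyntheticConfig, generate_reference, generate_truth


def make_unique_tag_reference(n_genes: int, rng: np.random.Generator):
    """Transcripts with exactly one CATG site each and mutually distant tags.

    Tails are drawn so that no two tags collide within Hamming distance 2,
    making every tag unambiguously attributable to its gene even under
    1-mismatch mapping.
    """
    bases = np.array(list("ACGT"))
    reference, tails = [], []
    i = 0
    while len(reference) < n_genes:
        tail = "".join(rng.choice(bases, size=17))
        if "CATG" in ("CATG" + tail) [1:]:
            continue
        if any(sum(a != b for a, b in zip(tail, t)) <= 2 for t in tails):
            continue
        tails.append(tail)
        prefix = "".join(rng.choice(np.array(list("ACT")), size=8))
        reference.append((f"G{i:04d}", prefix + "CATG" + tail))
        i += 1
    return reference


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_genes=80, library_depth=20_000, n_libraries=2, seed=11)


@pytest.fixture(scope="session")
def small_world(small_config):
    """Reference, index and truth for a small simulated experiment."""
    reference = generate_reference(small_config)
    index = build_index(reference)
    truth = generate_truth(small_config, reference, index=index)
    return reference, index, truth
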