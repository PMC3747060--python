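import numpy as np
import pytest

from mitopop.haplotyper import default_tree
from mitopop.refvar import Variant
from mitopop.synthdata import generate_nguni_fixture, synthetic_reference


@pytest.fixture(scope="session")
def reference_full():
    return synthetic_reference()


@pytest.fixture(scope="session")
def reference_small():
    return synthetic_reference(2000)


@pytest.fixture(scope="session")
def tree():
    return default_tree()


@pytest.fixture(scope="session")
def fixture_profiles(reference_full, tree):
    return generate_nguni_fixture(reference_full, tree)


def plant_random_variants(rng, reference, max_variants=30, spacing=10):
    """Plant a random, well-separated variant set suitable for exact
    alignment recovery: indels are kept out of homopolymer context so
    their placement is unambiguous."""
    L = len(reference)
    n = int(rng.integers(1, max_variants + 1))
    positions = []
    for p in rng.permutation(np.arange(50, L - 50)):
        p = int(p)
        if all(abs(p - q) >= spacing for q in positions):
            positions.append(p)
            if len(positions) == n:
                break
    variants = []
    for p in sorted(positions):
        base = reference.base(p)
        kind = int(rng.integers(3))
        if kind == 0:
            alts = [b for b in "ACGT" if b != base]
            variants.append(Variant.substitution(p, base, alts[int(rng.integers(3))]))
        elif kind == 1:
            alts = [b for b in "ACGT" if b != base and b != reference.base(p + 1)]
            variants.append(Variant.insertion(p, alts[int(rng.integers(len(alts)))]))
        elif reference.base(p - 1) == base or reference.base(p + 1) == base:
            alts = [b for b in "ACGT" if b != base]
            variants.append(Variant.substitution(p, base, alts[int(rng.integers(3))]))
        else:
            variants.append(Variant.deletion(p, base))
    return variants
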