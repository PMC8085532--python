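import pytest

from azfc import (
    CopyNumberVector,
    DepthSimSpec,
    default_reference_map,
    make_toy_map,
    reference_copy_vector,
    simulate_depth,
)

# the copy-number state of the rearranged chromosome:
# b=4, t=0, g=5, r=6, y=4, Gr=2, spacer absent
REARRANGED_VECTOR = CopyNumberVector(4, 0, 5, 6, 4, 2, 0)


@pytest.fixture(scope="session")
def refmap():
    return default_reference_map()


@pytest.fixture(scope="session")
def toy_map(refmap):
    """1% scale map: kilobase segments, fast enough for per-base simulation."""
    return make_toy_map(0.01, refmap)


@pytest.fixture(scope="session")
def rearranged_vector():
    return REARRANGED_VECTOR


@pytest.fixture(scope="session")
def reference_vector(refmap):
    return reference_copy_vector(refmap)


@pytest.fixture(scope="session")
def noiseless_rearranged_profile(toy_map):
    spec = DepthSimSpec(toy_map, REARRANGED_VECTOR, base_coverage=30.0,
                        noise="none", seed=0)
    return simulate_depth(spec, "noiseless")


@pytest.fixture(scope="session")
def poisson_rearranged_profile(toy_map):
    spec = DepthSimSpec(toy_map, REARRANGED_VECTOR, base_coverage=30.0,
                        noise="poisson", seed=11)
    return simulate_depth(spec, "rearranged")
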