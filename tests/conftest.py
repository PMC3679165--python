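import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from propellerscan import (
    AnnotatedRepeat,
    build_profile,
    default_profile,
    generate_wd40,
)


@pytest.fixture(scope="session")
def profile():
    """The packaged default profile."""
    return default_profile()


@pytest.fixture(scope="session")
def trained_profile(profile):
    """A profile retrained from repeats sampled out of the default profile;
    exercises the full training path on realistic data."""
    repeats = []
    for s in range(30):
        truth = generate_wd40(profile, n_repeats=7, seed=9000 + s,
                              sequence_id=f"train_{s}")
        repeats.extend(truth.annotated_repeats())
    return build_profile(repeats, provenance="session-trained")


def make_repeat(sequence: str, sd: int, sa: int, sb: int, sc: int,
                source_id: str = "toy") -> AnnotatedRepeat:
    return AnnotatedRepeat(
        sequence=sequence,
        strand_starts={"Sd": sd, "Sa": sa, "Sb": sb, "Sc": sc},
        source_id=source_id,
    )
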