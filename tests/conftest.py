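import string

import pytest

from pooldeconv.design import LibrarySpec, build_design
from pooldeconv.simulate import SimConfig, SimLibrary

# Two-letter, letter-only codes usable in clone names.
SIM_CODES = ["L" + c for c in string.ascii_uppercase] + ["M" + c for c in string.ascii_uppercase]

# The five-library, 789-plate collection from the published screening design
# (two of the libraries share a code in print; distinct codes are required for
# clone naming, matching the sub-pool names RP_HB/HI/HD/BB plus RI).
FIVE_LIBRARIES = [
    LibrarySpec("RI", 141, 1.6),
    LibrarySpec("HB", 156, 1.6),
    LibrarySpec("BB", 200, 1.9),
    LibrarySpec("HI", 156, 1.8),
    LibrarySpec("HD", 136, 1.6),
]


@pytest.fixture(scope="session")
def five_lib_design():
    """789 plates over a 27x30 super-pool matrix, one sub-pool per library."""
    return build_design(FIVE_LIBRARIES, (27, 30))


def clean_sim_config(seed: int, n_markers: int = 200, **overrides) -> SimConfig:
    """A screening regime with many ~0.17x one-plate sub-pools (4x total
    coverage) and a sparse 10x10 matrix: the setting where deconvolution is
    expected to be exact on error-free data."""
    kwargs = dict(
        genome_length=230_400.0,
        libraries=tuple(SimLibrary(SIM_CODES[i], 1, 100.0, 10.0) for i in range(24)),
        n_markers=n_markers,
        seed=seed,
        band_site_density=1.0,
        matrix_shape=(10, 10),
        min_tp_per_marker=2,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)
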