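import numpy as np
import pytest

from corrisk import make_table

# The worked LDL-C statin example: 60 patients per arm, unfavorable outcome
# is cholesterol >= 70 mg/dL at 18 months.  Referent row first.
TRIAL_COUNTS = (54, 6, 48, 12, 36, 24)

# The same trial scaled down by 6 so that the full multinomial support
# (n = 30) can be enumerated exhaustively.
SCALED_COUNTS = (9, 1, 8, 2, 6, 4)


@pytest.fixture(scope="session")
def trial_table():
    return make_table(TRIAL_COUNTS)


@pytest.fixture(scope="session")
def scaled_table():
    return make_table(SCALED_COUNTS)


@pytest.fixture(scope="session")
def null_table():
    """Three identical arms: both relative risks are exactly 1."""
    return make_table((30, 30, 30, 30, 30, 30))


def random_valid_tables(rng: np.random.Generator, k: int, low: int = 1, high: int = 200):
    """Yield k tables with all six cells positive (so RR and OR both exist)."""
    made = 0
    while made < k:
        cells = rng.integers(low, high, size=6)
        table = make_table([int(x) for x in cells])
        # skip the measure-zero case of a non-positive zeta denominator
        a11, a12, a21, a22, a31, a32 = (int(x) for x in cells)
        denom = 1 / a21 - 1 / (a21 + a22) + 1 / a31 - 1 / (a31 + a32)
        if denom <= 0:
            continue
        made += 1
        yield table
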