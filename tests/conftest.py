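import random

import pytest

from trz.catalog import default_catalog
from trz.synthetic import safe_linker_alphabet


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def safe_alphabet(catalog):
    return safe_linker_alphabet(catalog)


@pytest.fixture()
def rng():
    return random.Random(20110723)


def brute_force_scan(sequence, model):
    """Independent window-enumeration oracle for scan_motif."""
    m = len(model)
    hits = []
    forced = set(model.forced_mismatch_positions)
    for i in range(len(sequence) - m + 1):
        mismatches = 0
        forced_ok = True
        for k in range(m):
            match = model.matches_at(sequence[i + k], k)
            if not match:
                mismatches += 1
            if k in forced and match:
                forced_ok = False
        if forced_ok and mismatches <= model.max_mismatches:
            hits.append((i, i + m, mismatches))
    return hits
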