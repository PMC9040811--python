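import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from qsmine.synthetic_data import default_cohort_spec, make_cohort


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """The default 12-genome synthetic cohort, built once per session."""
    out = tmp_path_factory.mktemp("cohort")
    ledger = make_cohort(default_cohort_spec(seed=7), out)
    return out, ledger


@pytest.fixture(scope="session")
def profiles():
    from qsmine.conservation import load_profiles

    return load_profiles()


@pytest.fixture(scope="session")
def motifs():
    from qsmine.conservation import load_motifs

    return load_motifs()
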