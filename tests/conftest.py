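import numpy as np
import pytest

from contraflow.codes import CodeMap, tutorial_codemap
from contraflow.synth import cohort_from_flow_table, tutorial_flow_table


@pytest.fixture(scope="session")
def codes() -> CodeMap:
    """Full default DHS-dialect code map."""
    return CodeMap()


@pytest.fixture(scope="session")
def tut_codes() -> CodeMap:
    """Code map restricted to the five worked-example methods."""
    return tutorial_codemap()


@pytest.fixture(scope="session")
def tut_table():
    """The printed worked-example flow table (1,207 hypothetical women)."""
    return tutorial_flow_table()


@pytest.fixture(scope="session")
def tut_records(tut_table, tut_codes):
    """Unit-weight synthetic calendars realizing the worked-example table."""
    return cohort_from_flow_table(tut_table, tut_codes)


def random_calendar(rng: np.random.Generator, codes: CodeMap, length: int) -> str:
    """A random chronological state string over methods, non-use, and blanks."""
    alphabet = list(codes.method_codes) + [codes.nonuse_code] * 4 + [" "]
    return "".join(rng.choice(alphabet, size=length))
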