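import pytest

from lolliprot import AlignmentSet, make_ret_like_fixture


def make_alignment(rows: dict[str, str], reference_id: str = "ref") -> AlignmentSet:
    """Build an AlignmentSet from {id: aligned sequence}."""
    return AlignmentSet(records=list(rows.items()), reference_id=reference_id)


@pytest.fixture(scope="session")
def ret_fixture():
    """Deterministic RET-like inputs shared across tests (read-only)."""
    return make_ret_like_fixture()
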