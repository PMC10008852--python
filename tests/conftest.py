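import pytest

from mtbmatch import (
    build_paper_fixture,
    load_knowledge_base,
    minimal_kb_path,
    paper_kb_path,
    run_profiles,
)


@pytest.fixture(scope="session")
def kb_paper():
    return load_knowledge_base(paper_kb_path())


@pytest.fixture(scope="session")
def kb_minimal():
    return load_knowledge_base(minimal_kb_path())


@pytest.fixture(scope="session")
def paper_fixture(kb_paper):
    """(fixture_cases, case_profiles, expression_matrix)."""
    return build_paper_fixture(kb_paper)


@pytest.fixture(scope="session")
def cohort_run(paper_fixture, kb_paper):
    """(reports, summary) of the 14-case worked cohort."""
    _, profiles, expression = paper_fixture
    return run_profiles(profiles, kb_paper, expression=expression)
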