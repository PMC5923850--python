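import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def case_results():
    """Run each tabulated scenario at default numerics once per session.

    Returned as a lazy cache: ``results("A")`` gives the CaseResult for case
    A at 60 s; ``results("A", t_end=240.0)`` the extended run.  Several test
    modules share these, and each full-resolution case takes seconds.
    """
    from scaldsim import case_library, run_case

    library = case_library()
    cache: dict = {}

    def results(case_id: str, t_end: float | None = None):
        key = (case_id, t_end)
        if key not in cache:
            scenario = library[case_id]
            if t_end is not None:
                scenario = scenario.extended(t_end)
            cache[key] = run_case(scenario)
        return cache[key]

    return results
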