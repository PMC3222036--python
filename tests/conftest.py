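import pytest
from hypothesis import HealthCheck, settings

from vapbench.group_data import GroupRecord

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def toy_groups() -> list[GroupRecord]:
    """A small mixed evidence base covering every stratum and covariate."""
    return [
        GroupRecord("b1", "benchmark", "benchmark", 58, 264,
                    bronchoscopic_diagnosis=True, trauma_proportion=0.12,
                    mv_lt90=False, source_review="george"),
        GroupRecord("b2", "benchmark", "benchmark", 20, 83,
                    bronchoscopic_diagnosis=False, trauma_proportion=0.35,
                    mv_lt90=False, source_review="george"),
        GroupRecord("b3", "benchmark", "benchmark", 110, 567,
                    bronchoscopic_diagnosis=True, trauma_proportion=0.02,
                    mv_lt90=True, source_review="safdar"),
        GroupRecord("s1", "control", "sdd", 24, 57,
                    bronchoscopic_diagnosis=False, trauma_proportion=0.34,
                    mv_lt90=False, quality_majority=True, duplex=True,
                    source_review="liberati"),
        GroupRecord("s1", "intervention", "sdd", 8, 57,
                    bronchoscopic_diagnosis=False, trauma_proportion=0.34,
                    mv_lt90=False, quality_majority=True,
                    source_review="liberati"),
        GroupRecord("s2", "control", "sdd", 28, 60,
                    bronchoscopic_diagnosis=True, trauma_proportion=0.5,
                    mv_lt90=None, quality_majority=False, concurrent=False,
                    source_review="liberati"),
        GroupRecord("n1", "control", "non_antimicrobial", 10, 54,
                    bronchoscopic_diagnosis=False, trauma_proportion=0.15,
                    mv_lt90=False, quality_majority=True,
                    source_review="cook"),
        GroupRecord("n1", "intervention", "non_antimicrobial", 7, 50,
                    bronchoscopic_diagnosis=False, trauma_proportion=0.15,
                    mv_lt90=False, quality_majority=True,
                    source_review="cook"),
    ]
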