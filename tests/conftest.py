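import pytest
from hypothesis import HealthCheck, settings

from bjscreen.cohort import Cohort, SampleRecord

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def tiny_cohort():
    """Six hand-built samples: two kappa clones, one lambda clone, three
    negatives, spanning both sides of the rule-out window."""
    return Cohort(records=[
        SampleRecord("s1", "p1", 100.0, 50.0, 0.1, "negative", egfr=82.0,
                     age=70.0, sex="M"),
        SampleRecord("s2", "p2", 500.0, 10.0, 2.5, "kappa_bjp",
                     urine_mprotein=3000.0, egfr=60.0, age=75.0, sex="F"),
        SampleRecord("s3", "p3", 800.0, 12.0, 1.8, "kappa_bjp",
                     urine_mprotein=4200.0, egfr=90.0, age=66.0, sex="M"),
        SampleRecord("s4", "p4", 8.0, 400.0, 3.1, "lambda_bjp",
                     urine_mprotein=5100.0, egfr=70.0, age=80.0, sex="F"),
        SampleRecord("s5", "p5", 10.0, 11.0, 0.05, "negative", egfr=95.0,
                     age=55.0, sex="M"),
        SampleRecord("s6", "p6", 12.0, 12.0, 0.08, "negative", egfr=100.0,
                     age=62.0, sex="F"),
    ], name="tiny", source="observed")
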