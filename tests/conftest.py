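"""Shared fixtures: small hand-built records and a default synthetic cohort."""

from __future__ import annotations

import pytest
from hypothesis import settings

from sbdtriage import (
    HistologyFindings,
    PatientRecord,
    SimulationConfig,
    default_reference_ranges,
    generate_cohort,
)

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ranges():
    return default_reference_ranges()


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort (n=467, seed 1)."""
    return generate_cohort(SimulationConfig(seed=1))


def make_record(
    patient_id: str = "P0",
    age: int = 55,
    sex: str = "female",
    sbd: bool | None = None,
    **kwargs,
) -> PatientRecord:
    """A valid record with optional overrides; ``sbd`` picks a histology."""
    if sbd is True:
        kwargs.setdefault(
            "histology",
            HistologyFindings(
                cancer=False,
                adenoma_count=1,
                max_adenoma_size_mm=14.0,
                villous_component=False,
                high_grade_dysplasia=False,
                ibd=False,
            ),
        )
    elif sbd is False:
        kwargs.setdefault(
            "histology",
            HistologyFindings(
                cancer=False,
                adenoma_count=0,
                max_adenoma_size_mm=0.0,
                villous_component=False,
                high_grade_dysplasia=False,
                ibd=False,
                normal=True,
            ),
        )
    return PatientRecord(patient_id=patient_id, age=age, sex=sex, **kwargs)
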