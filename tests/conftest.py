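from __future__ import annotations

import math

import pytest
from hypothesis import HealthCheck, settings

from pb212pk.biodist import AnimalRecord, CohortTable, OrganSample
from pb212pk.decay import pb212_chain

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def chain():
    return pb212_chain()


def make_animal(
    animal_id="m1",
    compound="test",
    timepoint_h=4.0,
    organ_counts=None,
    mass_g=1.0,
    standard_counts=1e6,
    standard_fraction=0.01,
    injection_time_h=0.0,
    standard_count_time_h=0.0,
    counting_delay_h=0.0,
) -> AnimalRecord:
    """Hand-buildable animal record; counts given per organ."""
    organ_counts = organ_counts or {"tumor": 1e4, "kidney": 1e4}
    samples = tuple(
        OrganSample(
            organ=o,
            mass_g=mass_g if not isinstance(mass_g, dict) else mass_g[o],
            net_counts=c,
            count_time_h=timepoint_h + counting_delay_h,
            collection_time_h=timepoint_h,
        )
        for o, c in organ_counts.items()
    )
    return AnimalRecord(
        animal_id=animal_id,
        compound=compound,
        injection_time_h=injection_time_h,
        injected_standard_counts=standard_counts,
        standard_fraction=standard_fraction,
        standard_count_time_h=standard_count_time_h,
        samples=samples,
        nominal_timepoint_h=timepoint_h,
    )


@pytest.fixture
def tiny_cohort() -> CohortTable:
    """Noise-free 2-animals-per-timepoint cohort, equal T and K counts."""
    lam = math.log(2) / 10.64
    records = []
    for tp in (1.0, 4.0, 24.0):
        for i in (1, 2):
            # choose counts so to_injection %ID/g is exactly 10 for both organs
            s0 = 1e6 / 0.01  # injected-dose-equivalent counts at t=0
            counts = 10.0 / 100.0 * s0 * math.exp(-lam * tp)
            records.append(
                make_animal(
                    animal_id=f"a{tp:g}-{i}",
                    timepoint_h=tp,
                    organ_counts={"tumor": counts, "kidney": counts},
                )
            )
    return CohortTable(study_id="tiny", records=records)
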