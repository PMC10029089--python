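"""Shared fixtures: compact builders for patients and cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from tp53allelic.core_io import (
    CytoRecord,
    Effect,
    PatientRecord,
    RunConfig,
    Subtype,
    VariantCall,
)


def make_patient(
    pid: str = "P1",
    vafs=(),
    del17p: bool = False,
    clonality=None,
    upd17p: bool = False,
    complex_karyotype: bool = False,
    os_months: float = 12.0,
    os_event: bool = True,
    subtype: Subtype = Subtype.pAML,
    with_cyto: bool = True,
) -> PatientRecord:
    """One patient from bare numbers; cyto record omitted on request."""
    variants = tuple(
        VariantCall(pid, Effect.missense, float(v), None) for v in vafs
    )
    cyto = None
    if with_cyto:
        cyto = CytoRecord(
            patient_id=pid,
            del17p=del17p,
            del17p_clonality=clonality,
            upd17p=upd17p,
            complex_karyotype=complex_karyotype,
        )
    return PatientRecord(
        patient_id=pid,
        subtype=subtype,
        os_months=os_months,
        os_event=os_event,
        variants=variants,
        cyto=cyto,
    )


@pytest.fixture
def default_config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230309)


def random_survival_data(rng: np.random.Generator, n: int, censor: float = 0.3):
    """Continuous times (no ties a.s.), Bernoulli censoring."""
    times = rng.exponential(10.0, size=n)
    events = rng.random(n) > censor
    return times, events
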