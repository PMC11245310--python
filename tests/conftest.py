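import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")

from affinomap.affinity import AffinityValue, BaitConcentration
from affinomap.fragmentomics import AffinityProfile


@pytest.fixture
def bait10():
    """10 uM immobilized bait, the native-holdup slurry concentration."""
    return BaitConcentration.from_micromolar(10.0)


@pytest.fixture
def bait4():
    """4 uM purified SH3 domain, the fragmentomic-holdup analyte concentration."""
    return BaitConcentration.from_micromolar(4.0)


def make_profile(pks, censored=None, bait_id="WT", detection_pk=4.0):
    """Small affinity profile on a generic peptide panel."""
    pks = list(pks)
    if censored is None:
        censored = [False] * len(pks)
    values = [
        AffinityValue(pk=detection_pk if c else p, censored=c)
        for p, c in zip(pks, censored)
    ]
    return AffinityProfile(
        bait_id=bait_id,
        panel=[f"pep{i}" for i in range(len(pks))],
        values=values,
        detection_pk=detection_pk,
    )


@pytest.fixture
def profile_factory():
    return make_profile


def brute_force_scan(sequence):
    """Exhaustive sliding-window oracle for class 1/2 PxxP matching.

    Tests every 7-mer against [RK]..P..P and every 6-mer against P..P.[RK]
    position by position; returns (start_1based, class_id, core) sorted.
    """
    rk = set("RK")
    out = []
    for i in range(len(sequence)):
        w7 = sequence[i : i + 7]
        if len(w7) == 7 and w7[0] in rk and w7[3] == "P" and w7[6] == "P":
            out.append((i + 1, 1, w7))
        w6 = sequence[i : i + 6]
        if len(w6) == 6 and w6[0] == "P" and w6[3] == "P" and w6[5] in rk:
            out.append((i + 1, 2, w6))
    return sorted(out)
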