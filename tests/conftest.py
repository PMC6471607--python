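import pytest

from chairrise import LabelTrack, SubjectProfile, generate_session


@pytest.fixture(scope="session")
def easy_bundle():
    """One low-noise synthetic session with a valid five-rise test."""
    return generate_session(SubjectProfile(seed=101, fitness=0.6, noise_sd=0.1))


@pytest.fixture(scope="session")
def noisefree_bundle():
    """Noise-free session for exact phase-recovery checks."""
    return generate_session(SubjectProfile(seed=11, fitness=0.6, noise_sd=0.0))


def make_track(*cycle_counts, rise=1.0, descent=1.0, stand=0.5, sit=0.5,
               lead=2.0, final_descent=True):
    """Build a label track with the given number of rise/descent cycles."""
    segs = [(0.0, lead, "SIT")]
    t = lead
    n = cycle_counts[0] if cycle_counts else 5
    for i in range(n):
        segs.append((t, t + rise, "SIT_STAND")); t += rise
        last = i == n - 1
        if last and not final_descent:
            break
        if stand > 0:
            segs.append((t, t + stand, "STAND")); t += stand
        segs.append((t, t + descent, "STAND_SIT")); t += descent
        if not last and sit > 0:
            segs.append((t, t + sit, "SIT")); t += sit
    segs.append((t, t + 2.0, "SIT"))
    return LabelTrack(segs)


@pytest.fixture
def canonical_track():
    """5 x (SIT_STAND, STAND, STAND_SIT, SIT) with a leading/trailing sit."""
    return make_track(5)
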