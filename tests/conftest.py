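import numpy as np
import pytest
from hypothesis import settings

from rdsnet import ParticipantRecord, SimulationConfig, build_forest, generate_dataset

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def make_record(pid, recruiter=None, **kw):
    defaults = dict(
        channel="facebook" if recruiter else "unknown",
        completed=True,
        age=25,
        gender="female",
        education="bachelor",
        household_size=3,
        travel_contacts={"bus": 2},
        location_contacts={"home": 3, "work": 5},
        eating_contacts={"lunch": 2},
    )
    defaults.update(kw)
    return ParticipantRecord(pid=pid, recruiter_pid=recruiter, **defaults)


@pytest.fixture
def chain_records():
    """s -> a -> b -> c -> d -> e -> f : six recruitment links."""
    pids = ["s", "a", "b", "c", "d", "e", "f"]
    return [make_record(p, r) for p, r in zip(pids, [None] + pids[:-1])]


@pytest.fixture
def star_records():
    """One seed recruiting four children."""
    return [make_record("s")] + [make_record(f"c{i}", "s") for i in range(4)]


def random_forest_records(rng, n=40, p_child=0.75, max_coupons=4):
    """Random recruitment forest: each new node attaches to a random
    earlier node with spare coupons (else becomes a seed)."""
    records = [make_record("n000")]
    out_deg = {"n000": 0}
    for i in range(1, n):
        pid = f"n{i:03d}"
        candidates = [p for p, d in out_deg.items() if d < max_coupons]
        if candidates and rng.random() < p_child:
            parent = candidates[rng.integers(len(candidates))]
            out_deg[parent] += 1
            records.append(make_record(pid, parent))
        else:
            records.append(make_record(pid))
        out_deg[pid] = 0
    return records


@pytest.fixture(scope="session")
def synthetic_cohort():
    """Mid-sized synthetic dataset at the default study-like parameters."""
    records = generate_dataset(SimulationConfig(rng_seed=20240117))
    return records, build_forest(records)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(991)
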