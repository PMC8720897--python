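import numpy as np
import pytest

from minitag.simulator import simulate_community, simulate_references, simulate_reads
from minitag.tag_design import DesignConfig, expand_design


@pytest.fixture(scope="session")
def small_design():
    """Reduced design: 2 single containers, 1 leaf, both markers, both rounds."""
    return DesignConfig(
        single_containers=("I", "1"),
        double_containers=(),
        n_leaf_samples=1,
    )


@pytest.fixture(scope="session")
def small_plans(small_design):
    return expand_design(small_design)


@pytest.fixture(scope="session")
def ref_sets():
    return {
        "16S": simulate_references(10, "16S", seed=101),
        "ITS": simulate_references(8, "ITS", seed=202),
    }


@pytest.fixture(scope="session")
def raw_profiles(ref_sets, small_plans):
    profiles = {}
    for marker in ("16S", "ITS"):
        samples = sorted({p.sample_id for p in small_plans if p.marker == marker})
        profiles[marker] = {
            s: simulate_community(ref_sets[marker], "raw", seed=i, sample_id=s)
            for i, s in enumerate(samples)
        }
    return profiles


def make_pool(ref_sets, profiles, plans, n_per_lib, error_rates, chimera_rate, seed):
    """Simulate a pooled read set across both markers with a merged truth table."""
    import pandas as pd

    from minitag.io_formats import Read

    reads, frames = [], []
    for marker in sorted({p.marker for p in plans}):
        m_plans = [p for p in plans if p.marker == marker]
        r, t = simulate_reads(
            {marker: ref_sets[marker]},
            profiles[marker],
            m_plans,
            n_per_lib,
            error_rates,
            chimera_rate,
            seed=seed + (0 if marker == "16S" else 1),
        )
        reads.extend(Read(f"{marker}_{x.read_id}", x.sequence, x.quality) for x in r)
        t = t.copy()
        t["read_id"] = marker + "_" + t["read_id"]
        frames.append(t)
    return reads, pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def clean_pool(ref_sets, raw_profiles, small_plans):
    """Error-free pooled reads over all 20 small-design libraries."""
    return make_pool(
        ref_sets, raw_profiles, small_plans, 25,
        {"sub": 0, "ins": 0, "del": 0}, 0.0, seed=31,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
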