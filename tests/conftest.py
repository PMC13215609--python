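import pandas as pd
import pytest

from chronomem import entropy_engine as ee
from chronomem import synthetic_behavior as sb
from chronomem.stimulus_sampler import SamplingPlan, sample_stimuli


@pytest.fixture(scope="session")
def default_net():
    return ee.build_network(ee.NetworkConfig(seed=1))


@pytest.fixture(scope="session")
def fixture_batch(default_net):
    """100 fixture images scored once; reused by the engine invariants."""
    images = ee.generate_fixture_images(100, seed=11)
    traces = [ee.run_image(default_net, img, image_id) for image_id, img in images]
    return images, traces


@pytest.fixture(scope="session")
def score_table():
    return sb.make_synthetic_score_table(5000, seed=0)


@pytest.fixture(scope="session")
def score_table_uniform_a():
    return sb.make_synthetic_score_table(5000, seed=0, a_dist="uniform")


@pytest.fixture(scope="session")
def slow_stimuli(score_table):
    return sample_stimuli(score_table, SamplingPlan(strategy="slow_speed"), seed=1)


@pytest.fixture(scope="session")
def fast_stimuli(score_table_uniform_a):
    return sample_stimuli(
        score_table_uniform_a, SamplingPlan(strategy="high_speed_memorability"), seed=1
    )


@pytest.fixture(scope="session")
def slow_test_scores(slow_stimuli):
    rec = slow_stimuli.records
    return rec[rec["image_id"].isin(slow_stimuli.test)].reset_index(drop=True)


@pytest.fixture(scope="session")
def fast_test_scores(fast_stimuli):
    rec = fast_stimuli.records
    return rec[rec["image_id"].isin(fast_stimuli.test)].reset_index(drop=True)


def toy_score_table(rng, n, mem_lo=0.2, mem_hi=1.0):
    """Small random score table for oracle comparisons."""
    return pd.DataFrame(
        {
            "image_id": [f"t{i:03d}" for i in range(n)],
            "memorability": rng.uniform(mem_lo, mem_hi, n),
            "A": rng.normal(0.0, 1.0, n),
        }
    )
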