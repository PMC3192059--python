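import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from isoscreen import SampleManifest
from isoscreen.pipeline import PipelineConfig, run_pipeline
from isoscreen.simulate import SimulationConfig, simulate_experiment
from isoscreen.types import ExpressionMatrix, FoldChangeTable

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


def make_manifest(reference="H9", clones=("c1", "c2"), unrelated=(), somatic=()):
    names = [reference, *clones, *unrelated, *somatic]
    roles = (["reference_es"] + ["isogenic_clone"] * len(clones)
             + ["unrelated_ipsc"] * len(unrelated) + ["somatic"] * len(somatic))
    return SampleManifest(pd.Series(roles, index=pd.Index(names, name="sample")))


def make_fct(deltas, reference="H9", samples=None, ladder=(1.5, 2.0, 5.0, 10.0, 50.0)):
    """Fold-change table from a dict gene -> per-sample deltas (ref col zero)."""
    df = pd.DataFrame(deltas).T
    df.columns = samples or [f"c{i + 1}" for i in range(df.shape[1])]
    df.insert(0, reference, 0.0)
    df.index.name = "gene"
    return FoldChangeTable(df, reference, ladder)


@pytest.fixture(scope="session")
def default_sim():
    return simulate_experiment(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_bundle(default_sim):
    s = default_sim
    return run_pipeline(s.expression, s.annotation, s.manifest, s.ct,
                        s.methylation, PipelineConfig(seed=7,
                                                      hotspot_permutations=2000))


@pytest.fixture
def rng():
    return np.random.default_rng(123)
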