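import time

import numpy as np
import pytest

from icemob.panel import default_panel
from icemob.pipeline import PipelineConfig, evaluate, run_pipeline
from icemob.simulate import default_benchmark_scenario, simulate_mobilome


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def benchmark(tmp_path_factory):
    """The standard five-genome benchmark, simulated and analysed once.

    Everything downstream of this fixture exercises the full pipeline on
    genomes with planted ground truth.
    """
    out = tmp_path_factory.mktemp("benchmark_results")
    t0 = time.monotonic()
    genomes, truth = simulate_mobilome(default_benchmark_scenario(seed=1))
    cfg = PipelineConfig(out_dir=str(out), verbosity=0)
    result = run_pipeline(genomes, cfg)
    report = evaluate(result, truth)
    elapsed = time.monotonic() - t0
    return {"genomes": genomes, "truth": truth, "cfg": cfg, "result": result,
            "report": report, "elapsed": elapsed, "out_dir": str(out)}


@pytest.fixture()
def rng():
    return np.random.default_rng(20210657)
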