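"""Shared fixtures: the planted-truth world and one full pipeline run.

The world is the package's reference study condition (20 criterion-
satisfying hairpins, 5 decoys per violated rule, 20 known miRNAs, two
libraries); generating it and running the pipeline are expensive, so both
are session-scoped and reused across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from mirnod.pipeline import PipelineConfig, run
from mirnod.simulate import SimulationConfig, generate_world


@pytest.fixture(scope="session")
def world7():
    return generate_world(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def world7_dir(world7, tmp_path_factory):
    d = tmp_path_factory.mktemp("world7") / "world"
    world7.write(d)
    return d


@pytest.fixture(scope="session")
def pipeline7(world7_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle7") / "out"
    return run(PipelineConfig.for_world_dir(world7_dir), out), out


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_seq(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
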