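import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from ceact.pipeline import RunConfig, run_all, simulate
from ceact.synthetic import SimConfig, read_truth_table


def random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture(scope="session")
def demo_dataset(tmp_path_factory):
    """Small simulated study reused across pipeline-level tests.

    40 homolog pairs at 2% divergence with a fixed fold-change grid and
    2000 reads per population: enough coverage that every pair is
    quantified, small enough to run in seconds.
    """
    out = tmp_path_factory.mktemp("demo")
    grid = [-3, -2, -1, 0, 1, 2, 3]
    sim = SimConfig(
        n_transcripts=40,
        len_range=(400, 800),
        divergence=0.02,
        expr_log2fc=[grid[i % 7] for i in range(40)],
        reads_per_population=2000,
        seed=5,
    )
    paths = simulate(sim, out / "data")
    cfg = RunConfig(
        transcripts_a=str(paths["transcripts_a"]),
        transcripts_b=str(paths["transcripts_b"]),
        reads_a=str(paths["reads_a"]),
        reads_b=str(paths["reads_b"]),
        out_dir=str(out / "run"),
    )
    result = run_all(cfg)
    truth = read_truth_table(paths["truth"])
    return {"sim": sim, "paths": paths, "config": cfg, "result": result, "truth": truth}
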