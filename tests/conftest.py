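import os

import pytest

from sigscan.config import load_config
from sigscan.fixtures import FixtureSpec, generate
from sigscan.pipeline import run_pipeline


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A small planted-motif fixture shared by read-only tests."""
    d = str(tmp_path_factory.mktemp("fixture"))
    fasta, data_dir, gt_path, gt = generate(
        FixtureSpec(seed=11, n_proteins=10, n_placements=6), d)
    return {"dir": d, "fasta": fasta, "data_dir": data_dir,
            "gt_path": gt_path, "gt": gt}


@pytest.fixture()
def run(tmp_path):
    """Run the pipeline on a fixture with a fixed date, returning the
    PipelineResult."""
    counter = {"n": 0}

    def _run(fasta, data_dir, **kw):
        counter["n"] += 1
        out = tmp_path / f"run{counter['n']}" / "out"
        cfg = load_config(input=str(fasta), data_dir=str(data_dir),
                          output_base=str(out), date="2020-01-01", **kw)
        return run_pipeline(cfg)

    return _run


def read_bytes(path):
    with open(path, "rb") as fh:
        return fh.read()


@pytest.fixture()
def file_bytes():
    return read_bytes
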