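import numpy as np
import pandas as pd
import pytest

from spongetx.io_models import CountTable
from spongetx.synthetic_data import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A desk-scale synthetic dataset shared across read-only tests."""
    cfg = SynthConfig(seed=7, n_genes=400, n_reads=6000)
    return generate_dataset(cfg)


@pytest.fixture()
def toy_gff(tmp_path):
    """Three genes on two contigs, written 1-based inclusive."""
    text = "\n".join([
        "##gff-version 3",
        "c1\tsrc\tgene\t1\t100\t.\t+\t.\tID=gA",
        "c1\tsrc\texon\t1\t50\t.\t+\t.\tID=gA.e1;Parent=gA",
        "c1\tsrc\texon\t41\t80\t.\t+\t.\tID=gA.e2;Parent=gA",
        "c1\tsrc\texon\t91\t100\t.\t+\t.\tID=gA.e3;Parent=gA",
        "c2\tsrc\tgene\t201\t400\t.\t-\t.\tID=gC",
        "c2\tsrc\texon\t201\t400\t.\t-\t.\tID=gC.e1;Parent=gC",
        "c1\tsrc\tgene\t501\t700\t.\t+\t.\tID=gB",
        "c1\tsrc\texon\t501\t700\t.\t+\t.\tID=gB.e1;Parent=gB",
        "",
    ])
    path = tmp_path / "toy.gff3"
    path.write_text(text)
    return path


def make_table(values, samples=("PRE", "COMP", "POST", "ADULT"),
               totals=None, normalized=True) -> CountTable:
    """Counts from a dict gene -> per-stage values."""
    frame = pd.DataFrame.from_dict(values, orient="index", columns=list(samples))
    frame.index.name = "gene_id"
    totals = totals or {s: 1e5 for s in samples}
    return CountTable(frame.astype(float), totals, normalized=normalized)
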