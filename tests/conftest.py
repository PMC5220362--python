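import warnings
from types import SimpleNamespace

import numpy as np
import pytest

from cotransfer.io import bundle_from_dataset
from cotransfer.phylo import Phylogeny
from cotransfer.pipeline import PipelineConfig, run_pipeline
from cotransfer.simulate import simulate_dataset


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """One full pipeline run under the default study conditions (seed 0):
    16 genomes, 2 Mb chromosomes, 1500 families, 5/12 kb segment caps."""
    cfg = PipelineConfig().with_seed(0)
    ds = simulate_dataset(cfg.simulation)
    outdir = tmp_path_factory.mktemp("study_run")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_pipeline(cfg, outdir, inputs=bundle_from_dataset(ds))
    return SimpleNamespace(cfg=cfg, ds=ds, res=res, outdir=outdir)


@pytest.fixture(scope="session")
def tiny_tree():
    """Hand-built 4-leaf caterpillar: (((A:1,B:1):1,C:2):1,D:3);"""
    #        0
    #      /   \
    #     1     6(D)
    #   /   \
    #  2     5(C)
    # / \
    # 3  4
    parent = [-1, 0, 1, 2, 2, 1, 0]
    blen = [0.0, 1.0, 1.0, 1.0, 1.0, 2.0, 3.0]
    labels = [None, None, None, "A", "B", "C", "D"]
    return Phylogeny(np.array(parent), np.array(blen), labels)
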