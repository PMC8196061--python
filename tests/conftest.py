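import numpy as np
import pytest

from softcomp.corpus import train_codebooks
from softcomp.fixtures import FixtureSpec, generate_corpus


@pytest.fixture(scope="session")
def rgb_corpus(tmp_path_factory):
    """Seed-0 color corpus: 30 training and 20 test PNGs, 64x64."""
    outdir = tmp_path_factory.mktemp("rgb_corpus")
    spec = FixtureSpec(seed=0, height=64, width=64, components=3)
    train_paths, test_paths = generate_corpus(spec, 30, 20, outdir)
    return spec, train_paths, test_paths


@pytest.fixture(scope="session")
def rgb_codebooks(rgb_corpus):
    _, train_paths, _ = rgb_corpus
    cbs, log = train_codebooks(train_paths, corpus_id="rgb-seed0")
    return cbs, log


@pytest.fixture(scope="session")
def gray_corpus(tmp_path_factory):
    """Smaller grayscale corpus for single-component paths."""
    outdir = tmp_path_factory.mktemp("gray_corpus")
    spec = FixtureSpec(seed=7, height=32, width=32, components=1)
    train_paths, test_paths = generate_corpus(spec, 10, 5, outdir)
    return spec, train_paths, test_paths


@pytest.fixture(scope="session")
def gray_codebooks(gray_corpus):
    _, train_paths, _ = gray_corpus
    cbs, log = train_codebooks(train_paths, corpus_id="gray-seed7")
    return cbs, log


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
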