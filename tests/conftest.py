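"""Shared fixtures: synthetic corpora and the trained benchmark model."""

import pytest

import looptag as lt
from looptag.simulate import split_corpus

try:
    from hypothesis import settings

    settings.register_profile("suite", max_examples=30, deadline=None,
                              derandomize=True)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass


@pytest.fixture(scope="session")
def default_corpus():
    """The committed default synthetic corpus (seed 1) with bookkeeping."""
    return lt.generate_corpus(lt.GeneratorConfig())


@pytest.fixture(scope="session")
def benchmark(default_corpus):
    """200-sentence training / >=100-sentence held-out benchmark.

    Returns (train_sentences, dev_docs, trained_model, eval_result).
    """
    docs, _ = default_corpus
    train, dev = split_corpus(docs, 200, 100)
    model = lt.learn(lt.TaggerModel(), train, epochs=5, seed=1)
    preds = [lt.predict_document(model, d) for d in dev]
    result = lt.evaluate_spans(dev, preds)
    return train, dev, model, result


@pytest.fixture()
def tiny_doc():
    """Two-sentence document with two protein spans and one relation."""
    text = "p53 binds MDM2\nMDM2 inhibits p53"
    doc = lt.read_standoff(
        text,
        "T1\tprotein 0 3\tp53\n"
        "T2\tprotein 10 14\tMDM2\n"
        "T3\tprotein 15 19\tMDM2\n"
        "T4\tprotein 29 32\tp53\n"
        "R1\tLigand-receptor Arg1:T1 Arg2:T2\n",
        doc_id="tiny")
    return doc
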