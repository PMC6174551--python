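import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from chemrel.corpus_io import Document, EntityMention, EntityType, GoldRelation


@pytest.fixture
def fig2_style_doc():
    """A document whose first abstract sentence contains two chemical and
    two gene mentions with two gold positive relations — the canonical
    four-candidate-pairs situation."""
    title = "Blockade study ."
    abstract = (
        "UCCB01-125 is a potent inhibitor of PSD-95 unlike MK-801 which "
        "binds NMDAR directly . Control text follows here ."
    )
    doc = Document(pmid="42", title=title, abstract=abstract)
    text = doc.text("\t")

    def span(surface):
        start = text.index(surface)
        return start, start + len(surface)

    mentions = []
    for tid, surface, etype in [
        ("T1", "UCCB01-125", EntityType.CHEMICAL),
        ("T2", "MK-801", EntityType.CHEMICAL),
        ("T3", "PSD-95", EntityType.GENE),
        ("T4", "NMDAR", EntityType.GENE),
    ]:
        s, e = span(surface)
        mentions.append(EntityMention("42", tid, etype, s, e, surface))
    gold = [
        GoldRelation("42", "CPR:4", "T1", "T3"),
        GoldRelation("42", "CPR:6", "T2", "T4"),
    ]
    return doc, mentions, gold


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_corpus():
    from chemrel import synthetic

    return synthetic.generate(synthetic.SynthConfig(n_docs=12, seed=3))
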