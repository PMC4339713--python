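import numpy as np
import pandas as pd
import pytest

from osseoprofile.io_tables import AnnotationSet


def make_universe(lengths, term_members=None, domains=None):
    """Build an AnnotationSet from plain dicts (gene -> bp, term -> genes)."""
    term_members = term_members or {}
    rows = [
        {"gene_id": g, "term": t}
        for t, genes in term_members.items()
        for g in genes
    ]
    ann = pd.DataFrame(rows, columns=["gene_id", "term"])
    info = None
    if term_members:
        info = pd.DataFrame(
            {
                "name": ["" for _ in term_members],
                "domain": [
                    (domains or {}).get(t, "biological_process") for t in term_members
                ],
            },
            index=pd.Index(list(term_members), name="term"),
        )
    return AnnotationSet(
        lengths=pd.Series(lengths, name="length_bp"), annotations=ann, term_info=info
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)
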