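import numpy as np
import pandas as pd
import pytest

from mitoscreen.screen import CountTable, GuideAnnotation


@pytest.fixture
def tiny_annotation() -> GuideAnnotation:
    """Three targeting guides plus two nontargeting controls."""
    return GuideAnnotation(
        pd.DataFrame(
            {
                "target_gene": ["GENE1", "GENE1", "GENE2", None, None],
                "functional_class": [
                    "respiratory_chain",
                    "respiratory_chain",
                    "glycolytic",
                    "nontargeting",
                    "nontargeting",
                ],
            },
            index=pd.Index(["g1", "g2", "g3", "nt1", "nt2"], name="guide_id"),
        )
    )


def make_count_table(counts: dict[str, list[int]], guides, contexts=None, **meta_overrides) -> CountTable:
    samples = list(counts)
    contexts = contexts or {s: "in_vitro_day0" for s in samples}
    meta = pd.DataFrame(
        {
            "context": [contexts[s] for s in samples],
            "site": None,
            "day": [meta_overrides.get("day", {}).get(s, 0) for s in samples],
            "mouse_id": None,
            "experiment_id": [meta_overrides.get("experiment", {}).get(s, "exp1") for s in samples],
            "matched_primary": None,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    df = pd.DataFrame(counts, index=guides).astype(np.int64)
    return CountTable(df, meta)


@pytest.fixture
def make_counts():
    return make_count_table
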