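import pandas as pd
import pytest

import holotherm as ht
from holotherm.experiment_core import design_with_arm


@pytest.fixture(scope="session")
def micro():
    """Tiny noise-free fixture with hand-computable metrics."""
    return ht.generate_worked_microexample()


@pytest.fixture(scope="session")
def paper_assay():
    """One full synthetic experiment under the default study conditions."""
    return ht.generate(ht.paper_default_config(7))


@pytest.fixture(scope="session")
def paper_meta(paper_assay):
    """fragment_id → holobiont/arm/tank lookup for the session assay."""
    return design_with_arm(paper_assay.design).set_index("fragment_id")


def group_means(df: pd.DataFrame, meta: pd.DataFrame, value: str):
    """Mean of `value` per holobiont × arm (helper for recovery tests)."""
    merged = df.merge(meta[["holobiont", "arm"]], on="fragment_id")
    return merged.groupby(["holobiont", "arm"])[value].mean()
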