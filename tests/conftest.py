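import json

import pandas as pd
import pytest

from c4bpkit import synthetic as syn


@pytest.fixture(scope="session")
def xl_fixture(tmp_path_factory):
    """Synthetic cross-link fixture: toy PDB model, link table, manifest."""
    out = tmp_path_factory.mktemp("xl")
    paths = syn.gen_xl_fixture(seed=5, out_dir=out)
    paths["links_df"] = pd.read_csv(paths["links"], sep="\t")
    paths["manifest_data"] = json.loads(paths["manifest"].read_text())
    return paths


@pytest.fixture(scope="session")
def healthy_cohort():
    return syn.gen_plasma_cohort(scenario="healthy", sigma=0.0, seed=11)


@pytest.fixture(scope="session")
def default_psms():
    return syn.gen_glyco_psms(seed=3)
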