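import numpy as np
import pandas as pd
import pytest

from targetmr.gwas_io import SUMMARY_COLUMNS, SummaryTable


def make_table(rows, trait_name="trait", trait_type="continuous", unit="", build="GRCh38"):
    """Build a SummaryTable from dicts with sensible defaults."""
    full = []
    for i, r in enumerate(rows):
        d = dict(
            variant_id=f"rs{i}", chrom="16", pos=56_962_000 + i * 100,
            effect_allele="A", other_allele="G", eaf=0.3,
            beta=0.1, se=0.02, pvalue=1e-6, n=10_000,
        )
        d.update(r)
        full.append(d)
    df = pd.DataFrame(full)[SUMMARY_COLUMNS]
    return SummaryTable(trait_name, trait_type, unit, build, df)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_exposure():
    return make_table(
        [
            dict(variant_id="rs1", pos=56_962_000, beta=0.30, se=0.02, pvalue=1e-50, eaf=0.30),
            dict(variant_id="rs2", pos=56_962_100, beta=0.25, se=0.02, pvalue=1e-35, eaf=0.25),
            dict(variant_id="rs3", pos=56_962_200, beta=-0.20, se=0.02, pvalue=1e-22, eaf=0.40),
            dict(variant_id="rs4", pos=56_962_300, beta=0.15, se=0.02, pvalue=1e-12, eaf=0.20),
            dict(variant_id="rs5", pos=56_962_400, beta=0.10, se=0.02, pvalue=1e-6, eaf=0.45),
        ],
        trait_name="protein",
        unit="ug/ml",
    )
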