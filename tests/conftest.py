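import numpy as np
import pandas as pd
import pytest

from phosphodiff import (
    FeatureTable,
    StudyDesign,
    SyntheticConfig,
    generate,
    PROTEOME,
)


def build_design(lines: dict[str, str], replicates: int = 3) -> StudyDesign:
    rows = []
    for line, group in lines.items():
        for rep in range(1, replicates + 1):
            rows.append({"sample_id": f"{line}_{rep}", "cell_line": line,
                         "replicate": rep, "group": group})
    return StudyDesign(pd.DataFrame(rows).set_index("sample_id"))


FOUR_LINES = {"BEN": "benign", "CSL": "CS", "CRA": "CR", "CRB": "CR"}


@pytest.fixture
def design4() -> StudyDesign:
    return build_design(FOUR_LINES)


def make_table(values: np.ndarray, design: StudyDesign, *, ibaq=None,
               flags=None, genes=None, layer=PROTEOME) -> FeatureTable:
    """Small FeatureTable from a dense array (NaN = missing)."""
    n = values.shape[0]
    ids = [f"P{i:03d}" for i in range(n)]
    ratios = pd.DataFrame(values, index=ids, columns=design.samples)
    kwargs = {}
    if ibaq is not None:
        kwargs["ibaq"] = pd.DataFrame(ibaq, index=ids, columns=design.samples)
    if flags is not None:
        kwargs["flags"] = pd.DataFrame(flags, index=ids,
                                       columns=["contaminant", "reverse",
                                                "only_identified_by_site"])
    if genes is not None:
        kwargs["gene_symbols"] = pd.Series(genes, index=ids)
    return FeatureTable(ratios=ratios, design=design, layer=layer, **kwargs)


# A scaled-down generator configuration used where many replicate runs are
# needed; block structure is preserved, sizes are reduced.
SMALL_CONFIG = dict(
    n_proteins=400, n_sites=400,
    n_housekeeping=30, n_de_per_line=10, n_common_de=6, n_cr_de=16,
    n_cr_only=5, n_cs_only=4, n_cr_only_sites=3, n_cs_only_sites=4,
    n_sites_cr_de=10, n_kinases=10, substrates_per_kinase=6,
    n_modules=4, module_size=8, n_complexes=30,
)


@pytest.fixture(scope="session")
def default_run():
    """One default-size synthetic dataset shared across read-only tests."""
    cfg = SyntheticConfig(seed=11)
    prot, phos, truth = generate(cfg)
    return cfg, prot, phos, truth
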