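import numpy as np
import pandas as pd
import pytest

from radsens import CountMatrix, breast_design, generate_cohort, prostate_design


@pytest.fixture
def write_tsv(tmp_path):
    """Write a small count table to a temp TSV and return its path."""

    def _write(rows, header, name="counts.tsv"):
        path = tmp_path / name
        lines = ["gene_id\t" + "\t".join(header)]
        for gene, values in rows:
            lines.append(gene + "\t" + "\t".join(str(v) for v in values))
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def nb_matrix():
    """Random 20-gene x 4-sample negative-binomial count matrix."""
    rng = np.random.default_rng(42)
    mu = rng.lognormal(5, 1.2, size=20)
    counts = np.column_stack(
        [rng.negative_binomial(10, 10 / (10 + mu * s)) for s in (1.0, 0.7, 1.4, 1.1)]
    )
    return CountMatrix(
        pd.DataFrame(
            counts,
            index=[f"G{i}" for i in range(20)],
            columns=[f"S{j}" for j in range(4)],
        )
    )


@pytest.fixture(scope="session")
def breast_cohort():
    """One generated single-patient cohort: 9 tumour / 3 normal biopsies."""
    cfg = breast_design(seed=7)
    cm, sheet, truth = generate_cohort(cfg)
    return cfg, cm, sheet, truth


@pytest.fixture(scope="session")
def prostate_cohort():
    """One generated 14-patient paired cohort."""
    cfg = prostate_design(seed=11)
    cm, sheet, truth = generate_cohort(cfg)
    return cfg, cm, sheet, truth
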