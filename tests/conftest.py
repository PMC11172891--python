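import numpy as np
import pandas as pd
import pytest

from tearomics import (
    MicrobiomeSimConfig,
    ProteinGroupTable,
    ProteomeSimConfig,
    SampleAnnotation,
    TaxonAbundanceTable,
    simulate_microbiome,
    simulate_proteome,
)


def make_annotation(n_pat=4, n_ctl=4, sexes=None):
    """Small balanced annotation for unit tests."""
    rows = []
    for i in range(n_pat):
        rows.append((f"P{i+1:02d}", "patient",
                     (sexes or ["female", "male"])[i % 2], 75.0))
    for i in range(n_ctl):
        rows.append((f"C{i+1:02d}", "control",
                     (sexes or ["female", "male"])[i % 2], 68.0))
    df = pd.DataFrame(rows, columns=["sample_id", "group", "sex", "age"])
    return SampleAnnotation(df.set_index("sample_id"))


def make_protein_table(values, peptide_counts=None, contaminant=None,
                       sample_ids=None, scale="log2"):
    """Protein table from a 2-D array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    n_p, n_s = values.shape
    idx = pd.Index([f"PG{i+1:04d}" for i in range(n_p)], name="protein_id")
    cols = sample_ids or [f"S{j+1:02d}" for j in range(n_s)]
    return ProteinGroupTable(
        intensities=pd.DataFrame(values, index=idx, columns=cols),
        peptide_counts=pd.Series(peptide_counts if peptide_counts is not None
                                 else [5] * n_p, index=idx),
        contaminant=pd.Series(contaminant if contaminant is not None
                              else [False] * n_p, index=idx),
        scale=scale,
    )


@pytest.fixture(scope="session")
def default_proteome():
    """Default synthetic cohort: 2250 proteins, 16/16 samples, MNAR censoring."""
    return simulate_proteome(ProteomeSimConfig(seed=7))


@pytest.fixture(scope="session")
def complete_proteome():
    """Censoring-free cohort (midpoint far below all intensities)."""
    cfg = ProteomeSimConfig(censor_midpoint=-1e6, censor_slope=1.0, seed=7)
    return simulate_proteome(cfg)


@pytest.fixture(scope="session")
def default_microbiome():
    return simulate_microbiome(MicrobiomeSimConfig(seed=7))


@pytest.fixture()
def toy_abundance():
    """Hand-sized percent-scale abundance table with known lineages."""
    taxa = [
        "k__Bacteria|p__Actinobacteria|g__Cutibacterium|s__Cutibacterium_acnes",
        "k__Bacteria|p__Actinobacteria|g__Corynebacterium|s__Corynebacterium_mastitidis",
        "k__Bacteria|p__Firmicutes|g__Staphylococcus|s__Staphylococcus_aureus",
        "k__Bacteria|p__Firmicutes|g__Streptococcus|s__Streptococcus_mitis",
    ]
    data = np.array(
        [
            [60.0, 50.0, 40.0, 55.0],
            [10.0, 5.0, 0.0, 0.0],
            [25.0, 40.0, 59.5, 44.5],
            [5.0, 5.0, 0.5, 0.5],
        ]
    )
    cols = ["P01", "P02", "C01", "C02"]
    return TaxonAbundanceTable(pd.DataFrame(data, index=pd.Index(taxa, name="lineage"),
                                            columns=cols), unit="percent")
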