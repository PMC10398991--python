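import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from neuromethyl import annotation as ann
from neuromethyl import synthetic
from neuromethyl.datamodel import MethylationDataset, ProbeAnnotation


@pytest.fixture(scope="session")
def small_universe():
    """1,000-gene universe with 20% neural and 10% bivalent genes."""
    return synthetic.generate_universe(
        n_genes=1000, probes_per_gene=2, neural_fraction=0.2, bivalent_fraction=0.1, seed=11
    )


@pytest.fixture(scope="session")
def planted_run(small_universe):
    """Synthetic two-group dataset with 150 planted hyper genes (40% neural)."""
    annotation, go, sets, truth0 = small_universe
    dataset, truth = synthetic.generate_methylation(
        annotation,
        truth0,
        n_hyper=150,
        n_hypo=50,
        effect_m=3.0,
        neural_enrichment=0.4,
        n_normal=12,
        n_tumor=12,
        seed=12,
    )
    flags = ann.classify(go)
    return annotation, dataset, truth, flags, sets


def tiny_methylation(beta_rows, samples_groups):
    """Hand-built dataset: beta_rows is {probe: [values]}, groups per column."""
    beta = pd.DataFrame.from_dict(beta_rows, orient="index")
    beta.columns = [f"s{i}" for i in range(beta.shape[1])]
    samples = pd.DataFrame(
        {"group": samples_groups, "cancer_type": "T"},
        index=pd.Index(beta.columns, name="sample_id"),
    )
    return MethylationDataset(beta=beta, samples=samples)


def tiny_annotation(pairs, island=None):
    """pairs: list of (probe, gene, region)."""
    df = pd.DataFrame(pairs, columns=["probe_id", "gene_id", "region"])
    probes = df["probe_id"].unique()
    isl = pd.Series(
        {p: bool(island[p]) if island else False for p in probes}, name="island"
    )
    return ProbeAnnotation(pairs=df, island=isl)
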