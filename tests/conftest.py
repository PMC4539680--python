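import pandas as pd
import pytest

from aascan.annotate import GeneModel
from aascan.synth import SyntheticConfig, simulate


def small_config(seed=11, **overrides):
    """A fast, down-scaled cohort that still exercises every stage."""
    kw = dict(
        seed=seed,
        n_cancers=2,
        samples_per_cancer=12,
        n_genes=150,
        drivers_per_cancer=4,
        background_rate=60.0,
        n_pathways=8,
        pathway_size=4,
        n_go_terms=10,
        network_density=0.01,
    )
    kw.update(overrides)
    return SyntheticConfig(**kw)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate(small_config())


@pytest.fixture()
def toy_gene():
    """Single-exon plus-strand gene at genomic 101..121 (ATG CGT TGG CGA TCA TAA + pad).

    Protein: M R W R S; reference has 100 bases of padding before the CDS.
    """
    cds = "ATGCGTTGGCGATCATAA"
    ref = "A" * 100 + cds + "G" * 50
    model = GeneModel("G1", "T1", "+", ((101, 100 + len(cds)),))
    return model, {"chr1": ref}


def make_variants(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "cancer_type", "chrom", "pos", "ref", "alt"]
    )


def aas_frame(rows):
    """Minimal AAS-record frame for modules that only need a few columns."""
    cols = [
        "sample_id",
        "cancer_type",
        "protein_id",
        "residue_pos",
        "ref_aa",
        "alt_aa",
        "consequence",
    ]
    return pd.DataFrame(rows, columns=cols)
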