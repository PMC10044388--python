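import numpy as np
import pandas as pd
import pytest

from carrierpanel import FounderVariantSpec, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def clean_two_pop():
    """Two populations, no trios/duplicates/errors/missingness; planted founders."""
    cfg = SimulationConfig(
        population_sizes=(500, 400),
        population_names=("ashkenazi", "arab"),
        fst_per_population=0.05,
        n_background_variants=800,
        founder_variant_specs=(
            FounderVariantSpec("ashkenazi", 0.02, gene="GENEA"),
            FounderVariantSpec("arab", 0.01, gene="GENEB"),
            FounderVariantSpec("ashkenazi", 0.004, gene="GENEC", inheritance="XL"),
        ),
        n_trios_per_population=0,
        n_duplicates=0,
        label_error_rate=0.0,
        missing_rate=0.0,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def structured_cohort():
    """Cohort with trios, duplicates, label errors and missing calls."""
    cfg = SimulationConfig(
        population_sizes=(250, 250),
        fst_per_population=0.05,
        n_background_variants=4000,
        n_trios_per_population=8,
        n_duplicates=4,
        label_error_rate=0.05,
        missing_rate=0.02,
        seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def tiny_annotations():
    """Hand-built annotation table exercising the candidate filters."""
    rows = [
        # key, gene, classifications, inheritance, severity, af, hom
        ("1:100:A:G", "G1", "clinvar=P", "AR", "severe", 0.001, 0),
        ("1:200:A:G", "G2", "community=LP;clinvar=VUS", "AR", "severe", 0.002, 1),
        ("1:300:A:G", "G3", "clinvar=VUS", "AR", "severe", 0.001, 0),
        ("1:400:A:G", "G4", "clinvar=B;community=LB", "AR", "moderate", 0.2, 50),
        ("1:500:A:G", "G5", "clinvar=P", "AR", "mild", 0.001, 0),
        ("1:600:A:G", "G6", "clinvar=P", "AR", "severe", 0.006, 0),
        ("1:700:A:G", "G7", "clinvar=P", "AR", "severe", 0.005, 2),
        ("1:800:A:G", "G8", "clinvar=LP", "AR", "severe", 0.001, 3),
        ("X:900:A:G", "G9", "community=P", "XL", "severe", 0.0005, 0),
        ("1:1000:A:G", "G10", "", "AR", "", 0.3, 100),
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "variant_key", "gene", "classifications", "inheritance",
            "severity", "reference_overall_af", "reference_homozygote_count",
        ],
    ).set_index("variant_key")
    df["chrom"] = [k.split(":")[0] for k in df.index]
    df["pos"] = [int(k.split(":")[1]) for k in df.index]
    df["ref"] = "A"
    df["alt"] = "G"
    df["condition"] = ""
    return df
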