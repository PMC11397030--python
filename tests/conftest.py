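import numpy as np
import pandas as pd
import pytest

from pgscov import GenotypePanel, SummaryStats, SyntheticScenario, VariantKey, simulate_panel


def make_stats(rows):
    """Build SummaryStats from (chrom, pos, rsid, effect, other, beta, pvalue) tuples."""
    df = pd.DataFrame(rows, columns=[
        "chrom", "pos", "rsid", "effect_allele", "other_allele", "beta", "pvalue"])
    df["odds_ratio"] = np.exp(df["beta"])
    df["maf"] = 0.25
    return SummaryStats(df[list(SummaryStats.COLUMNS)])


def make_panel(dosage_columns, chrom="1", start=1000, spacing=1000, samples=None,
               rsid_offset=0, info=None):
    """Panel from a dict/list of dosage columns at evenly spaced positions."""
    cols = np.column_stack([np.asarray(c, dtype=float) for c in dosage_columns])
    n = cols.shape[0]
    variants = [
        VariantKey(chrom, start + j * spacing, f"rs{rsid_offset + j + 1}", "A", "G")
        for j in range(cols.shape[1])
    ]
    return GenotypePanel(
        variants=variants,
        samples=samples or [f"S{i + 1}" for i in range(n)],
        dosages=cols,
        info=info,
    )


@pytest.fixture(scope="session")
def small_scenario():
    return SyntheticScenario(n_blocks=6, block_size=10, n_founders=6, flip_prob=0.01,
                             n_samples=300, n_causal=8, effect_sd=0.4, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_scenario):
    return simulate_panel(small_scenario)
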