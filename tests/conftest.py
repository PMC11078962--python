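import numpy as np
import pandas as pd
import pytest

from mrscreen.harmonize import from_arrays
from mrscreen.sumstats import SummaryDataset, TraitMeta


@pytest.fixture
def fixed_harmonized():
    """A deterministic 5-SNP harmonized set used across estimator tests."""
    beta_x = np.array([0.12, -0.08, 0.15, 0.05, -0.20])
    se_x = np.array([0.01, 0.012, 0.011, 0.009, 0.015])
    beta_y = np.array([0.06, -0.03, 0.09, 0.01, -0.11])
    se_y = np.array([0.02, 0.025, 0.022, 0.018, 0.03])
    return from_arrays(beta_x, se_x, beta_y, se_y)


def make_dataset(rows, trait_id="trait", trait_type="quantitative",
                 n_total=10_000, n_cases=None):
    """Build a SummaryDataset from a list of row dicts (test helper)."""
    defaults = dict(chrom="1", pos=1, effect_allele="A", other_allele="G",
                    eaf=0.3, beta=0.1, se=0.02, n=float(n_total))
    full = []
    for i, r in enumerate(rows):
        d = dict(defaults)
        d.setdefault("snp", f"rs{i}")
        d.update(r)
        if "pval" not in d:
            from scipy import stats
            d["pval"] = float(2 * stats.norm.sf(abs(d["beta"] / d["se"])))
        full.append(d)
    columns = ["snp", "chrom", "pos", "effect_allele", "other_allele",
               "eaf", "beta", "se", "pval", "n"]
    df = pd.DataFrame(full, columns=columns)
    meta = TraitMeta(trait_id, trait_id, trait_type, n_total, n_cases)
    return SummaryDataset(meta, df)


@pytest.fixture
def rep_seeds():
    """Deterministic seed streams for Monte-Carlo tests."""
    def _make(label: str, n: int):
        root = int(np.frombuffer(label.encode().ljust(8, b"\0")[:8], dtype=np.uint32)[0])
        return np.random.SeedSequence(root).generate_state(n) % (2**31)
    return _make
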