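import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import cffkit as ck

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def coarse_genome():
    """1 Mb bins (~3000 bins): same chromosome shares, much faster draws."""
    return ck.default_genome_model(bin_size=1_000_000)


@pytest.fixture(scope="session")
def genome():
    """Full-resolution 50 kb bin table."""
    return ck.default_genome_model()


@pytest.fixture(scope="session")
def panel():
    """220-SNP panel: 40 SNPs on chr21, 180 on control autosomes."""
    return ck.shift_panel(seed=0)


def make_binned(counts_by_chrom, gc=0.45):
    """Tiny hand-built binned-count table."""
    rows = []
    for chrom, counts in counts_by_chrom.items():
        for i, (c, g) in enumerate(counts):
            rows.append(
                {"chrom": chrom, "start": i * 100, "end": (i + 1) * 100,
                 "gc": g if g is not None else gc, "count": c}
            )
    return pd.DataFrame(rows)


def per_snp_from_sim(spec, panel, depth=5000.0, error_rate=0.001):
    """Template-level per-SNP concentration table for one simulated sample."""
    pl = ck.simulate_template_pileups(spec, panel=panel, depth=depth,
                                      error_rate=error_rate)
    return ck.per_snp_ff(pl[pl["r_sum"] >= 100])


def shift_rejection_rate(f, trisomy, n_seeds, seed_base, panel, target="chr21"):
    """Empirical high-risk rate of the shift test over replicate samples."""
    rej = 0
    for s in range(n_seeds):
        spec = ck.MixtureSpec(f, trisomy_chrom=trisomy, seed=seed_base + s)
        call = ck.trisomy_shift_test(per_snp_from_sim(spec, panel), target)
        rej += call.call == "high_risk"
    return rej / n_seeds
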