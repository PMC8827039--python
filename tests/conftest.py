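"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-implementations (direct loops,
sort-and-scan) used to cross-check the package's vectorized code paths; they
must stay independent of the implementation they test.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pathlinc import SimulationConfig, generate_dataset
from pathlinc.io import ExpressionMatrix
from pathlinc.model import PathwayRegulationModel

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def tiny_expr() -> ExpressionMatrix:
    """5 genes x 6 samples with known structure, log2 scale."""
    rng = np.random.default_rng(7)
    samples = ["T1", "T2", "T3", "N1", "N2", "N3"]
    genes = ["gA", "gB", "gC", "LNC1", "TF1"]
    values = pd.DataFrame(rng.normal(5, 1, (5, 6)), index=genes,
                          columns=samples)
    return ExpressionMatrix(
        values=values,
        gene_classes=pd.Series(["mRNA", "mRNA", "mRNA", "lncRNA", "TF"],
                               index=genes),
        sample_groups=pd.Series(["tumor"] * 3 + ["control"] * 3,
                                index=samples),
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """One synthetic cohort with strongly-loaded planted regulators."""
    cfg = SimulationConfig(seed=3, regulator_loading=0.8)
    return cfg, generate_dataset(cfg)


@pytest.fixture(scope="session")
def fitted_results(planted_dataset):
    """Model fit of the planted cohort, shared across tests."""
    _, (expr, sets, loci, peaks, truth) = planted_dataset
    model = PathwayRegulationModel(expr, sets, loci=loci, peaks=peaks)
    return model.fit(seed=103), truth


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_es(rs, is_member, weight=1.0):
    """Direct running-sum walk over the whole list (definition of ES)."""
    rs = np.asarray(rs, dtype=float)
    is_member = np.asarray(is_member, dtype=bool)
    n = len(rs)
    n_hit = int(is_member.sum())
    assert 0 < n_hit
    denom = float(np.sum(np.abs(rs[is_member]) ** weight))
    if denom == 0.0:
        hit_steps = np.full(n_hit, 1.0 / n_hit)
    else:
        hit_steps = np.abs(rs[is_member]) ** weight / denom
    miss_step = 1.0 / (n - n_hit) if n > n_hit else 0.0
    run, best, hit_i = 0.0, 0.0, 0
    for i in range(n):
        if is_member[i]:
            run += hit_steps[hit_i]
            hit_i += 1
        else:
            run -= miss_step
        if abs(run) > abs(best):
            best = run
    return best


def bh_step_up(pvals):
    """Textbook BH: sort, scan from the largest, enforce monotonicity."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        value = min(prev, p[i] * n / rank)
        adjusted[i] = value
        prev = value
    return adjusted


def all_pairs_overlap(peak_sets, windows):
    """Exhaustive peak x window scan; windows = {gene: (chrom, lo, hi)}."""
    counts = {}
    for ps in peak_sets:
        for chrom, start, end in ps.intervals:
            for gene, (wchrom, lo, hi) in windows.items():
                if chrom == wchrom and max(start, lo) < min(end, hi):
                    counts[(ps.tf_id, gene)] = counts.get((ps.tf_id, gene), 0) + 1
    return counts


@pytest.fixture(scope="session")
def oracles():
    return {
        "brute_force_es": brute_force_es,
        "bh_step_up": bh_step_up,
        "all_pairs_overlap": all_pairs_overlap,
    }
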