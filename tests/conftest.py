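"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (per-read scans, brute-force
sums, hand-stepped loops) and share no code with the package paths they
check.
"""

import numpy as np
import pandas as pd
import pytest

from craave import LibraryTable, make_truth, simulate_library, simulate_screen_counts


# ---------------------------------------------------------------- oracles

def naive_count(reads, library, orientation="forward"):
    """Per-read scan over every protospacer; O(reads x guides)."""
    comp = str.maketrans("ACGT", "TGCA")
    counts = {sid: 0 for sid in library.entries["sgrna_id"]}
    unassigned = ambiguous = 0
    pairs = list(zip(library.entries["sgrna_id"], library.entries["protospacer"]))
    for read in reads:
        views = [read] if orientation == "forward" else [read, read.translate(comp)[::-1]]
        hits = {sid for sid, proto in pairs if any(proto in v for v in views)}
        if len(hits) == 1:
            counts[hits.pop()] += 1
        elif not hits:
            unassigned += 1
        else:
            ambiguous += 1
    return counts, unassigned, ambiguous


def brute_force_bh(pvalues):
    """BH step-up from the definition: adj_(k) = min over j>=k of p_(j)*n/j."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * n / rank_from_top)
        adjusted[idx] = running_min
    return adjusted


def hand_stepped_delta(q, is_amalgam):
    """Empirical FDR by explicit rank stepping on an already-ranked list.

    Amalgam entries increment the precedence count and keep their raw
    delta; the monotone chain runs over the real (reported) genes.
    """
    deltas = []
    c = 0
    prev_real = 0.0
    for i, (qi, am) in enumerate(zip(q, is_amalgam), start=1):
        if am:
            c += 1
        d = min(max(c / i, qi), 1.0)
        if not am:
            d = max(d, prev_real)
            prev_real = d
        deltas.append(d)
    return np.array(deltas)


def nb_pmf_sum(mu, sigma2, obs):
    """Brute-force NB tail probabilities by summing the pmf from moments."""
    from scipy.stats import nbinom

    r = mu**2 / (sigma2 - mu)
    p = mu / sigma2
    ks = np.arange(0, obs + 1)
    p_under = float(nbinom.pmf(ks, r, p).sum())
    p_over = 1.0 - float(nbinom.pmf(np.arange(0, obs), r, p).sum())
    return p_under, p_over


# ---------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def tiny_library():
    """Three targeting guides over two genes plus one NTC, fixed sequences."""
    return LibraryTable(
        pd.DataFrame(
            {
                "sgrna_id": ["geneA_sg1", "geneA_sg2", "geneB_sg1", "ntc_sg1"],
                "gene_group": ["geneA", "geneA", "geneB", "non-targeting"],
                "protospacer": [
                    "ACGTACGTACGTACGTACGT",
                    "TTTTCCCCGGGGAAAATTTT",
                    "GATTACAGATTACAGATTAC",
                    "CCCCCCCCCCGGGGGGGGGG",
                ],
                "is_ntc": [False, False, False, True],
            }
        )
    )


@pytest.fixture(scope="session")
def small_sim_library():
    return simulate_library(n_genes=50, guides_per_gene=5, n_ntc=25, seed=11)


@pytest.fixture(scope="session")
def standard_screen():
    """10% essential genes at effect -2; the generator's stated world."""
    lib = simulate_library(n_genes=500, guides_per_gene=5, n_ntc=250, seed=21)
    truth = make_truth(lib, essential_fraction=0.1, effect_size=-2.0, n_active=4, seed=22)
    counts, truth = simulate_screen_counts(
        lib, truth, n_mice=6, control_reps=3, depth=500.0, seed=23
    )
    return lib, truth, counts
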