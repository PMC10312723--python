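"""Cohort bootstrap: how many mice does a screen need?

Mice (treatment samples) are subsampled without replacement at every
cohort size from 1 to N, the full per-sgRNA + gene-aggregation pipeline
is rerun on each subset with the same parameters as the full-cohort
analysis, and each replicate's hit set is compared with the full-cohort
hits. A full-cohort hit's "recovery rate" at size s is the fraction of
the 50 replicates that re-identify it.

Control (AAV input) columns are always retained; only treatment columns
are subsampled. Replicate subsets are drawn from an RNG seeded by
(master seed, size, replicate) so adding sizes never reshuffles existing
replicates; the amalgam seed is a fixed derivation from the master seed,
re-derived identically in every replicate and in the full-cohort run, so
that a replicate holding the complete cohort reproduces the full-cohort
hit set exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geopagg import aggregate_genes
from .library import CountMatrix
from .sgrna_stats import analyze_sgrnas

__all__ = ["BootstrapReport", "bootstrap_screen", "recovery_table", "derive_amalgam_seed"]


def derive_amalgam_seed(master_seed: int) -> int:
    """Stable amalgam-RNG seed derived from the master seed (< 2^31)."""
    return int(np.random.SeedSequence([master_seed, 0xA3A16A3]).generate_state(1)[0] % (2**31))


def _replicate_rng(master_seed: int, size: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master_seed, size, rep]))


@dataclass
class BootstrapReport:
    """Bootstrap outcome across subset sizes.

    ``overlaps``: one row per (subset_size, replicate) with the replicate
    hit count and its overlap with the full-cohort hits (fraction of full
    hits recovered). ``recovery``: tidy (gene, subset_size, recovery_rate)
    for every full-cohort hit.
    """

    full_hits: list[str]
    overlaps: pd.DataFrame
    recovery: pd.DataFrame
    sizes: list[int]
    reps: int
    fdr: float
    seed: int
    replicate_hits: dict = field(default_factory=dict, repr=False)


def bootstrap_screen(
    counts: CountMatrix,
    sizes: Sequence[int] | None = None,
    reps: int = 50,
    fdr: float = 0.1,
    seed: int = 0,
    ntc_groups="non-targeting",
    amalgam_factor: int = 1,
    gamma_variant: str = "product",
    **analysis_kwargs,
) -> BootstrapReport:
    """Subsample mice at each cohort size and measure hit reproducibility.

    ``sizes`` defaults to 1..N (N = number of distinct mice). Duplicate
    subsets at small sizes are allowed: 50 replicates are drawn at every
    size regardless of how many distinct subsets exist.
    """
    mice = counts.mice
    n_mice = len(mice)
    if n_mice == 0:
        raise ValueError("no treatment samples to bootstrap")
    if sizes is None:
        sizes = list(range(1, n_mice + 1))
    sizes = [int(s) for s in sizes]
    too_big = [s for s in sizes if s > n_mice or s < 1]
    if too_big:
        raise ValueError(f"subset sizes out of range 1..{n_mice}: {too_big}")

    amalgam_seed = derive_amalgam_seed(seed)

    def run(subset: CountMatrix) -> set[str]:
        sg = analyze_sgrnas(subset, **analysis_kwargs)
        genes = aggregate_genes(
            sg.table,
            ntc_groups=ntc_groups,
            seed=amalgam_seed,
            amalgam_factor=amalgam_factor,
            gamma_variant=gamma_variant,
            fdr_threshold=fdr,
        )
        return genes.hit_genes

    full_hits = sorted(run(counts))
    if not full_hits:
        warnings.warn(
            "full-cohort analysis produced no hits; overlap fractions undefined",
            stacklevel=2,
        )

    mouse_samples = {m: [] for m in mice}
    for s in counts.treatment_samples:
        mouse_samples[counts.mouse_id.get(s, s)].append(s)
    control_cols = counts.control_samples

    overlap_rows = []
    rep_hits: dict[tuple[int, int], set[str]] = {}
    for s in sizes:
        for r in range(reps):
            rng = _replicate_rng(seed, s, r)
            chosen = set(rng.choice(np.asarray(mice, dtype=object), size=s, replace=False))
            cols = control_cols + [
                c for m in mice if m in chosen for c in mouse_samples[m]
            ]
            hits = run(counts.subset_samples(cols))
            rep_hits[(s, r)] = hits
            overlap = (
                len(hits & set(full_hits)) / len(full_hits) if full_hits else np.nan
            )
            overlap_rows.append((s, r, len(hits), overlap))

    overlaps = pd.DataFrame(
        overlap_rows, columns=["subset_size", "replicate", "n_hits", "overlap"]
    )
    recovery_rows = [
        (g, s, sum(g in rep_hits[(s, r)] for r in range(reps)) / reps)
        for g in full_hits
        for s in sizes
    ]
    recovery = pd.DataFrame(
        recovery_rows, columns=["gene_group", "subset_size", "recovery_rate"]
    )
    return BootstrapReport(
        full_hits=full_hits,
        overlaps=overlaps,
        recovery=recovery,
        sizes=sizes,
        reps=reps,
        fdr=fdr,
        seed=seed,
        replicate_hits=rep_hits,
    )


def recovery_table(report: BootstrapReport) -> pd.DataFrame:
    """Tidy (gene, subset_size, recovery_rate) table for heatmap plotting."""
    return report.recovery.copy()
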