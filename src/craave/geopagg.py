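"""geopagg: gene-level aggregation of sgRNA FDRs with an empirical null.

Per gene group, member sgRNA FDRs are combined by a weighted geometric
mean under "Drop-First" weighting (the best-FDR member gets weight 0.5,
all others 1.0) so that genes with multiple concordant guides outrank
genes carried by a single guide. Member phenotypes are averaged
arithmetically. Quasi-genes ("amalgam" genes) assembled from randomly
grouped non-targeting controls, matching the real genes' membership-size
distribution, serve as an empirical null: after sorting by the gene score
gamma = phi * (-log10 q), the empirical FDR at rank i is
max(amalgams_at_or_before_i / i, q_i), made monotone in rank. The whole
procedure runs separately on the under- and over-abundance FDRs and each
real gene reports its more significant direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "drop_first_weights",
    "weighted_geomean_fdr",
    "aggregate_phenotype",
    "build_amalgam",
    "gene_score",
    "empirical_fdr",
    "call_hits",
    "aggregate_genes",
    "GeneResults",
]

FDR_FLOOR = 1e-300

UNDER = "under"
OVER = "over"
DIRECTION_LABEL = {UNDER: "depleted", OVER: "enriched"}


def drop_first_weights(
    fdrs, phis=None, direction: str = UNDER, sgrna_ids=None
) -> np.ndarray:
    """Drop-First weight vector: 0.5 on the member with the minimum FDR,
    1.0 elsewhere.

    Exactly one member carries 0.5. FDR ties break toward the most extreme
    phenotype in the test's direction (most negative for under-abundance,
    most positive for over-abundance), then lexicographic sgrna_id.
    """
    x = np.asarray(fdrs, dtype=float)
    if x.size == 0:
        raise ValueError("empty member set")
    candidates = np.flatnonzero(x == x.min())
    if len(candidates) > 1 and phis is not None:
        phi = np.asarray(phis, dtype=float)[candidates]
        key = phi if direction == UNDER else -phi
        candidates = candidates[key == key.min()]
    if len(candidates) > 1 and sgrna_ids is not None:
        ids = np.asarray(sgrna_ids, dtype=object)[candidates]
        candidates = candidates[np.argsort(ids, kind="stable")[:1]]
    weights = np.ones_like(x)
    weights[candidates[0]] = 0.5
    return weights


def weighted_geomean_fdr(member_fdrs, weights=None, **tiebreak_kwargs) -> float:
    """Weighted geometric mean q = exp(sum_j w_j ln x_j / sum_j w_j).

    With ``weights=None`` the Drop-First weights are derived from the
    members themselves. Inputs are floored at 1e-300 before the log.
    """
    x = np.asarray(member_fdrs, dtype=float)
    if x.size == 0:
        raise ValueError("empty member set")
    if np.any(x <= 0) or np.any(x > 1):
        raise ValueError("member FDRs must lie in (0, 1]")
    if weights is None:
        weights = drop_first_weights(x, **tiebreak_kwargs)
    w = np.asarray(weights, dtype=float)
    logs = np.log(np.maximum(x, FDR_FLOOR))
    return float(np.exp(np.sum(w * logs) / np.sum(w)))


def aggregate_phenotype(member_phis) -> float:
    """Arithmetic-mean gene phenotype phi_i (unweighted by design)."""
    phi = np.asarray(member_phis, dtype=float)
    if phi.size == 0:
        raise ValueError("empty member set")
    return float(phi.mean())


def build_amalgam(
    ntc_sgrnas,
    membership_sizes,
    seed: int = 0,
    factor: int = 1,
) -> dict[str, list[str]]:
    """Assemble amalgam quasi-genes from non-targeting controls.

    One amalgam gene per entry of ``membership_sizes`` (times ``factor``),
    each drawing its members without replacement WITHIN the amalgam gene;
    the NTC pool is replenished between amalgam genes, since matching every
    real gene generally needs more draws than NTCs exist. Deterministic
    under ``seed``.
    """
    ntc_sgrnas = list(ntc_sgrnas)
    sizes = list(membership_sizes) * int(factor)
    if not ntc_sgrnas:
        raise ValueError("no non-targeting controls available for amalgam genes")
    if not sizes:
        raise ValueError("membership_sizes is empty")
    too_big = [m for m in sizes if m > len(ntc_sgrnas)]
    if too_big:
        raise ValueError(
            f"amalgam size {max(too_big)} exceeds the NTC pool ({len(ntc_sgrnas)})"
        )
    rng = np.random.default_rng(seed)
    pool = np.asarray(ntc_sgrnas, dtype=object)
    width = len(str(len(sizes)))
    return {
        f"amalgam_{k:0{width}d}": list(rng.choice(pool, size=m, replace=False))
        for k, m in enumerate(sizes, start=1)
    }


def gene_score(phi_i, q_i, variant: str = "product"):
    """Gene score gamma_i combining phenotype and significance.

    ``product`` (default): gamma = phi * (-log10 q) — a depleted gene with
    a small q sorts first in the ascending under-abundance list.
    ``additive``: gamma = phi - log10 q, for sensitivity analysis.
    """
    phi_i = np.asarray(phi_i, dtype=float)
    q = np.maximum(np.asarray(q_i, dtype=float), FDR_FLOOR)
    if variant == "product":
        return phi_i * (-np.log10(q))
    if variant == "additive":
        return phi_i - np.log10(q)
    raise ValueError(f"unknown gamma variant: {variant!r}")


def empirical_fdr(gamma, q, is_amalgam, direction: str = UNDER) -> np.ndarray:
    """Empirical FDR delta_i for a ranked gene list (real + amalgam).

    The list must already be sorted by gamma (ascending for the
    under-abundance test, descending for over-abundance); an unsorted
    input is an error. With c_i = number of amalgam genes at rank <= i,
    delta_i = max(c_i / i, q_i) capped at 1, then made non-decreasing in
    rank. The monotone constraint chains over the REAL genes (the
    reported list); amalgam entries contribute to c_i and carry their
    unchained delta as diagnostics — an amalgam landing at rank 1 (whose
    own c_i/i is 1 by construction) must not erase every gene after it.
    """
    gamma = np.asarray(gamma, dtype=float)
    q = np.asarray(q, dtype=float)
    is_amalgam = np.asarray(is_amalgam, dtype=bool)
    diffs = np.diff(gamma)
    if direction == UNDER:
        sorted_ok = np.all(diffs >= 0)
    elif direction == OVER:
        sorted_ok = np.all(diffs <= 0)
    else:
        raise ValueError(f"unknown direction: {direction!r}")
    if not sorted_ok:
        raise ValueError(
            f"gene list is not sorted by gamma for the {direction!r} test"
        )
    ranks = np.arange(1, len(gamma) + 1)
    c = np.cumsum(is_amalgam)
    delta = np.minimum(np.maximum(c / ranks, q), 1.0)
    real = ~is_amalgam
    delta[real] = np.maximum.accumulate(delta[real])
    return delta


@dataclass
class GeneResults:
    """Gene-level output of one geopagg run.

    ``genes``: one row per real gene group with its reported (most
    significant) direction. ``diagnostics``: the full ranked per-direction
    tables including amalgam genes. ``meta``: seed/thresholds used.
    """

    genes: pd.DataFrame
    diagnostics: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def hits(self) -> pd.DataFrame:
        return self.genes[self.genes["is_hit"]]

    @property
    def hit_genes(self) -> set[str]:
        return set(self.hits.index)


def _direction_table(members: pd.DataFrame, direction: str, gamma_variant: str) -> pd.DataFrame:
    """Aggregate a long member table (one row per gene-member) for one
    direction. ``members`` columns: gene_group, is_amalgam, sgrna_id, fdr, phi.
    """
    df = members.copy()
    df["fdr"] = np.maximum(df["fdr"].to_numpy(dtype=float), FDR_FLOOR)
    # Drop-First winner per gene: min fdr, tie -> extreme phi in direction,
    # tie -> lexicographic sgrna_id; vectorized via a stable sort.
    phi_key = df["phi"] if direction == UNDER else -df["phi"]
    order = np.lexsort(
        (df["sgrna_id"].to_numpy(dtype=object), phi_key.to_numpy(), df["fdr"].to_numpy())
    )
    df = df.iloc[order]
    winner = ~df.duplicated("gene_group", keep="first")
    df["w"] = np.where(winner, 0.5, 1.0)
    df["wlog"] = df["w"] * np.log(df["fdr"])

    grouped = df.groupby("gene_group", sort=False)
    agg = grouped.agg(
        M_i=("sgrna_id", "size"),
        is_amalgam=("is_amalgam", "first"),
        phi=("phi", "mean"),
        wlog=("wlog", "sum"),
        w=("w", "sum"),
    )
    agg["q"] = np.exp(agg["wlog"] / agg["w"])
    agg = agg.drop(columns=["wlog", "w"])
    agg["gamma"] = gene_score(agg["phi"], agg["q"], variant=gamma_variant)

    # Sort by gamma in the direction's order; ties -> smaller q, real
    # before amalgam, lexicographic id (recorded so delta is reproducible).
    sign = 1.0 if direction == UNDER else -1.0
    agg = agg.reset_index()
    order = np.lexsort(
        (
            agg["gene_group"].to_numpy(dtype=object),
            agg["is_amalgam"].to_numpy(),
            agg["q"].to_numpy(),
            sign * agg["gamma"].to_numpy(),
        )
    )
    agg = agg.iloc[order].reset_index(drop=True)
    agg["rank"] = np.arange(1, len(agg) + 1)
    agg["c_i"] = np.cumsum(agg["is_amalgam"].to_numpy())
    agg["delta"] = empirical_fdr(
        agg["gamma"].to_numpy(),
        agg["q"].to_numpy(),
        agg["is_amalgam"].to_numpy(),
        direction=direction,
    )
    agg["direction"] = direction
    return agg


def aggregate_genes(
    sgrna_table: pd.DataFrame,
    ntc_groups,
    seed: int = 0,
    amalgam_factor: int = 1,
    gamma_variant: str = "product",
    fdr_threshold: float = 0.1,
) -> GeneResults:
    """Run geopagg on a per-sgRNA results table.

    ``sgrna_table`` is indexed by sgrna_id with columns gene_group, phi,
    fdr_under, fdr_over (the :mod:`craave.sgrna_stats` output). Guides
    whose gene_group is in ``ntc_groups`` are the non-targeting pool that
    seeds the amalgam set; all other gene groups are scored as real genes
    (dual-TSS groups like GeneA_P1/GeneA_P2 independently).
    """
    if isinstance(ntc_groups, str):
        ntc_groups = {ntc_groups}
    ntc_groups = set(ntc_groups)

    tbl = sgrna_table
    is_ntc = tbl["gene_group"].isin(ntc_groups)
    real = tbl[~is_ntc]
    ntc_ids = list(tbl.index[is_ntc])
    if real.empty:
        raise ValueError("no targeting gene groups in the sgRNA table")

    sizes = real.groupby("gene_group", sort=False).size()
    amalgam = build_amalgam(ntc_ids, list(sizes), seed=seed, factor=amalgam_factor)
    amalgam_long = pd.DataFrame(
        [(g, sid) for g, members in amalgam.items() for sid in members],
        columns=["gene_group", "sgrna_id"],
    )

    genes_by_dir = {}
    diagnostics = []
    for direction, fdr_col in ((UNDER, "fdr_under"), (OVER, "fdr_over")):
        real_long = pd.DataFrame(
            {
                "gene_group": real["gene_group"].to_numpy(),
                "is_amalgam": False,
                "sgrna_id": real.index.to_numpy(),
                "fdr": real[fdr_col].to_numpy(dtype=float),
                "phi": real["phi"].to_numpy(dtype=float),
            }
        )
        am_long = amalgam_long.copy()
        am_long["is_amalgam"] = True
        am_long["fdr"] = tbl.loc[am_long["sgrna_id"], fdr_col].to_numpy(dtype=float)
        am_long["phi"] = tbl.loc[am_long["sgrna_id"], "phi"].to_numpy(dtype=float)
        members = pd.concat(
            [real_long, am_long[real_long.columns]], ignore_index=True
        )
        table = _direction_table(members, direction, gamma_variant)
        genes_by_dir[direction] = table
        diagnostics.append(table)

    # Combine: each real gene reports its more significant direction.
    per_dir = {
        d: t[~t["is_amalgam"]].set_index("gene_group") for d, t in genes_by_dir.items()
    }
    under, over = per_dir[UNDER], per_dir[OVER]
    under = under.loc[sorted(under.index)]
    over = over.loc[under.index]
    pick_under = under["delta"].to_numpy() <= over["delta"].to_numpy()
    chosen = under.where(pd.Series(pick_under, index=under.index), over)
    genes = pd.DataFrame(
        {
            "n_sgrnas": under["M_i"].astype(int),
            "phi": chosen["phi"].astype(float),
            "q_under": under["q"],
            "q_over": over["q"],
            "gamma": chosen["gamma"].astype(float),
            "direction": np.where(
                pick_under, DIRECTION_LABEL[UNDER], DIRECTION_LABEL[OVER]
            ),
            "empirical_fdr": chosen["delta"].astype(float),
        },
        index=under.index,
    )
    genes["is_hit"] = genes["empirical_fdr"] < fdr_threshold
    genes.index.name = "gene_group"

    return GeneResults(
        genes=genes,
        diagnostics=pd.concat(diagnostics, ignore_index=True),
        meta={
            "seed": seed,
            "amalgam_factor": amalgam_factor,
            "gamma_variant": gamma_variant,
            "fdr_threshold": fdr_threshold,
            "n_amalgam": len(amalgam),
            "n_ntc_sgrnas": len(ntc_ids),
        },
    )


def call_hits(results: GeneResults, threshold: float | None = None) -> pd.DataFrame:
    """Real genes whose reported empirical FDR falls below the threshold."""
    thr = results.meta.get("fdr_threshold", 0.1) if threshold is None else threshold
    genes = results.genes
    hits = genes[genes["empirical_fdr"] < thr].copy()
    if threshold is not None:
        hits["is_hit"] = True
    return hits
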