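"""Synthetic pooled-screen generator with recorded ground truth.

Emulates the count statistics the analysis assumes: an AAV input library
with long-tailed (log-normal) sgRNA abundances; control columns as
negative-binomial noise around the input; treatment (per-mouse episome)
columns as NB noise around input x 2^effect for the active guides of
essential genes, scaled by a per-mouse coverage factor; optional
low-titer mode that shrinks coverage and zero-inflates counts to mimic
dropout of both targeting and non-targeting guides. Non-targeting
controls are always null. The simulator targets count-matrix statistics
only — no spatial structure or per-cell modeling.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .library import CONTROL, TREATMENT, CountMatrix, LibraryTable

__all__ = [
    "SimTruth",
    "simulate_library",
    "make_truth",
    "simulate_screen_counts",
    "simulate_fastq",
    "PRESETS",
]

NTC_GROUP = "non-targeting"
_BASES = np.array(list("ACGT"))


def _random_protospacers(rng: np.random.Generator, n: int, length: int) -> list[str]:
    if n > 4**length:
        raise ValueError(f"cannot draw {n} distinct {length}-mers")
    seen: dict[str, None] = {}
    attempts = 0
    while len(seen) < n:
        block = rng.integers(0, 4, size=(n - len(seen), length))
        for row in block:
            seen.setdefault("".join(_BASES[row]), None)
        attempts += 1
        if attempts > 100:
            raise RuntimeError("duplicate-draw retries exhausted")
    return list(seen)[:n]


def simulate_library(
    n_genes: int,
    guides_per_gene: int | Sequence[int] = 5,
    n_ntc: int = 250,
    dual_tss_fraction: float = 0.0,
    seed: int = 0,
    protospacer_length: int = 20,
) -> LibraryTable:
    """Random sgRNA library with unique protospacers.

    ``guides_per_gene`` may be a per-gene sequence (length ``n_genes``) to
    emulate libraries with uneven guide coverage. A ``dual_tss_fraction``
    of genes is split into two independent ``_P1``/``_P2`` groups, each
    with the gene's full guide complement.
    """
    rng = np.random.default_rng(seed)
    if isinstance(guides_per_gene, int):
        sizes = [guides_per_gene] * n_genes
    else:
        sizes = list(guides_per_gene)
        if len(sizes) != n_genes:
            raise ValueError("guides_per_gene sequence must have length n_genes")
    n_dual = int(round(dual_tss_fraction * n_genes))
    dual = set(rng.choice(n_genes, size=n_dual, replace=False)) if n_dual else set()

    rows = []
    for g in range(n_genes):
        gene = f"gene{g + 1:05d}"
        groups = [f"{gene}_P1", f"{gene}_P2"] if g in dual else [gene]
        for grp in groups:
            for j in range(sizes[g]):
                rows.append((f"{grp}_sg{j + 1}", grp, False))
    for k in range(n_ntc):
        rows.append((f"ntc_sg{k + 1:04d}", NTC_GROUP, True))

    protos = _random_protospacers(rng, len(rows), protospacer_length)
    entries = pd.DataFrame(
        {
            "sgrna_id": [r[0] for r in rows],
            "gene_group": [r[1] for r in rows],
            "protospacer": protos,
            "is_ntc": [r[2] for r in rows],
        }
    )
    return LibraryTable(entries)


@dataclass
class SimTruth:
    """Ground truth of a simulated screen.

    ``genes``: per gene group — is_essential, effect_size (mean log2
    depletion of the active guides; <= 0 for essentials), n_active.
    ``guides``: per sgRNA — realized per-guide effect (0 for inactive and
    for every NTC). ``coverage``: per-mouse coverage factors, filled in by
    :func:`simulate_screen_counts`.
    """

    genes: pd.DataFrame
    guides: pd.DataFrame
    seed: int
    dispersion_alpha: float = 0.01
    input_sigma: float = 0.8
    coverage: dict[str, float] = field(default_factory=dict)

    @property
    def essential_genes(self) -> set[str]:
        return set(self.genes.index[self.genes["is_essential"]])


def make_truth(
    library: LibraryTable,
    essential_fraction: float = 0.1,
    effect_size: float = -2.0,
    n_active: int = 4,
    effect_jitter_sd: float = 0.25,
    dispersion_alpha: float = 0.01,
    input_sigma: float = 0.8,
    seed: int = 0,
) -> SimTruth:
    """Assign effects: a fraction of genes essential, with ``n_active`` of
    each gene's guides carrying the (jittered) effect; the rest null.
    """
    rng = np.random.default_rng(seed)
    entries = library.entries
    groups = library.gene_groups
    n_ess = int(round(essential_fraction * len(groups)))
    essential = set(rng.choice(np.asarray(groups, dtype=object), size=n_ess, replace=False))

    gene_rows = []
    guide_effect = pd.Series(0.0, index=pd.Index(entries["sgrna_id"], name="sgrna_id"))
    by_group = entries[~entries["is_ntc"]].groupby("gene_group", sort=False)
    for grp, sub in by_group:
        ess = grp in essential
        k = min(n_active, len(sub)) if ess else 0
        gene_rows.append((grp, ess, effect_size if ess else 0.0, k))
        if k:
            active = rng.choice(sub["sgrna_id"].to_numpy(), size=k, replace=False)
            guide_effect[active] = effect_size + rng.normal(0, effect_jitter_sd, size=k)
    genes = pd.DataFrame(
        gene_rows, columns=["gene_group", "is_essential", "effect_size", "n_active"]
    ).set_index("gene_group")
    guides = pd.DataFrame(
        {
            "gene_group": entries["gene_group"].to_numpy(),
            "effect": guide_effect.to_numpy(),
            "is_active": guide_effect.to_numpy() != 0.0,
        },
        index=guide_effect.index,
    )
    return SimTruth(
        genes=genes,
        guides=guides,
        seed=seed,
        dispersion_alpha=dispersion_alpha,
        input_sigma=input_sigma,
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Draw counts with var = mean + alpha * mean^2 (Poisson when alpha=0)."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = 1.0 / (1.0 + alpha * mean)
    return rng.negative_binomial(r, p)


def simulate_screen_counts(
    library: LibraryTable,
    truth: SimTruth,
    n_mice: int = 6,
    control_reps: int = 3,
    depth: float = 500.0,
    seed: int = 0,
    coverage_sd: float = 0.2,
    low_titer: bool = False,
    low_titer_coverage: float = 0.05,
    dropout_prob: float | None = None,
) -> tuple[CountMatrix, SimTruth]:
    """Simulate the count matrix of one screen.

    ``depth`` is the mean reads per sgRNA in the input library. Per-mouse
    coverage factors are log-normal with log-sd ``coverage_sd``; low-titer
    mode multiplies them by ``low_titer_coverage`` and zero-inflates each
    treatment count with probability ``dropout_prob`` (default 0.3 when
    low-titer, else 0).
    """
    rng = np.random.default_rng(seed)
    entries = library.entries
    n = len(entries)
    if dropout_prob is None:
        dropout_prob = 0.3 if low_titer else 0.0

    abundance = rng.lognormal(0.0, truth.input_sigma, size=n)
    abundance /= abundance.mean()
    base_mean = abundance * depth
    effect = truth.guides.loc[entries["sgrna_id"], "effect"].to_numpy()
    alpha = truth.dispersion_alpha

    data = {}
    roles = {}
    mice = {}
    for c in range(control_reps):
        name = f"AAV_{c + 1}"
        data[name] = _nb_draw(rng, base_mean, alpha)
        roles[name] = CONTROL
    coverage = {}
    for m in range(n_mice):
        name = f"mouse_{m + 1}"
        factor = float(np.exp(rng.normal(0.0, coverage_sd)))
        if low_titer:
            factor *= low_titer_coverage
        coverage[name] = factor
        mean = base_mean * np.exp2(effect) * factor
        col = _nb_draw(rng, mean, alpha)
        if dropout_prob > 0:
            col = np.where(rng.random(n) < dropout_prob, 0, col)
        data[name] = col
        roles[name] = TREATMENT
        mice[name] = name

    idx = pd.Index(entries["sgrna_id"], name="sgrna_id")
    counts = CountMatrix(
        counts=pd.DataFrame(data, index=idx, dtype=int),
        gene_group=pd.Series(entries["gene_group"].to_numpy(), index=idx, name="gene_group"),
        sample_role=roles,
        mouse_id=mice,
        unassigned={s: 0 for s in data},
        ambiguous={s: 0 for s in data},
    )
    truth.coverage = coverage
    return counts, truth


def simulate_fastq(
    column: pd.Series,
    library: LibraryTable,
    path: str | Path,
    read_length: int = 75,
    seed: int = 0,
) -> pd.Series:
    """Write a FASTQ(.gz) embedding each protospacer ``column[sgrna]`` times
    at a random offset in random background sequence; returns the true
    counts actually written (the bookkeeping for round-trip tests).

    Each read is checked to contain exactly its intended protospacer and
    no other library protospacer; colliding backgrounds are re-drawn.
    """
    rng = np.random.default_rng(seed)
    proto_of = dict(zip(library.entries["sgrna_id"], library.entries["protospacer"]))
    protos = set(proto_of.values())
    lengths = sorted({len(p) for p in protos})
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open

    def matches(read: str) -> set[str]:
        found = set()
        for L in lengths:
            for i in range(len(read) - L + 1):
                sub = read[i : i + L]
                if sub in protos:
                    found.add(sub)
        return found

    truth = {}
    read_no = 0
    with opener(path, "wt") as fh:
        for sgrna_id, n_reads in column.items():
            proto = proto_of[sgrna_id]
            n_reads = int(n_reads)
            if read_length < len(proto):
                raise ValueError("read_length shorter than protospacer")
            truth[sgrna_id] = n_reads
            for _ in range(n_reads):
                for _attempt in range(100):
                    offset = int(rng.integers(0, read_length - len(proto) + 1))
                    bg = "".join(rng.choice(_BASES, size=read_length))
                    read = bg[:offset] + proto + bg[offset + len(proto):]
                    if matches(read) == {proto}:
                        break
                else:
                    raise RuntimeError("could not place protospacer without collision")
                read_no += 1
                fh.write(f"@read{read_no} {sgrna_id}\n{read}\n+\n{'I' * read_length}\n")
    series = pd.Series(truth, name="count", dtype=int)
    series.index.name = "sgrna_id"
    return series


# Named simulation presets used by the CLI: (library kwargs, truth kwargs,
# screen kwargs). Library shapes follow the study's two real libraries.
PRESETS = {
    "null": dict(
        library=dict(n_genes=500, guides_per_gene=5, n_ntc=250),
        truth=dict(essential_fraction=0.0),
        screen=dict(n_mice=4, control_reps=3, depth=500.0),
    ),
    "standard": dict(
        library=dict(n_genes=500, guides_per_gene=5, n_ntc=250),
        truth=dict(essential_fraction=0.1, effect_size=-2.0, n_active=4),
        screen=dict(n_mice=6, control_reps=3, depth=500.0),
    ),
    "low-titer": dict(
        library=dict(n_genes=500, guides_per_gene=5, n_ntc=250),
        truth=dict(essential_fraction=0.1, effect_size=-2.0, n_active=4),
        screen=dict(n_mice=6, control_reps=3, depth=500.0, low_titer=True),
    ),
    # 2,420 gene groups x 5 guides + 250 NTCs = 12,350 entries
    "m1-shaped": dict(
        library=dict(n_genes=2420, guides_per_gene=5, n_ntc=250),
        truth=dict(essential_fraction=0.1, effect_size=-2.0, n_active=4),
        screen=dict(n_mice=6, control_reps=3, depth=500.0),
    ),
    # 354 genes, 1,830 targeting guides (60 genes carry 6), 350 NTCs = 2,180
    "chaperone-shaped": dict(
        library=dict(n_genes=354, guides_per_gene=[6] * 60 + [5] * 294, n_ntc=350),
        truth=dict(essential_fraction=0.1, effect_size=-2.0, n_active=4),
        screen=dict(n_mice=6, control_reps=3, depth=500.0),
    ),
}
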