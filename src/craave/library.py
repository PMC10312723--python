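"""sgRNA library parsing and exact-match read counting.

The counting model is deliberately strict: a read is assigned to a guide
only when exactly one library protospacer occurs as an exact substring of
the read (optionally also scanning the reverse complement). Reads matching
no protospacer are tallied as ``unassigned``; reads matching two or more
distinct protospacers are tallied as ``ambiguous`` and never fractionally
assigned. Base qualities are ignored and ``N`` never matches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "LibraryTable",
    "CountMatrix",
    "ReadCounts",
    "parse_library",
    "count_reads",
    "reverse_complement",
    "read_sample_sheet",
]

_VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

CONTROL = "control"
TREATMENT = "treatment"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LibraryTable:
    """Validated sgRNA reference library.

    ``entries`` has columns ``sgrna_id``, ``gene_group``, ``protospacer``,
    ``is_ntc``. Gene groups may carry ``_P1``/``_P2`` suffixes for guides
    targeting distinct transcription start sites of one gene; such groups
    are treated as fully independent genes downstream.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.entries
        required = ["sgrna_id", "gene_group", "protospacer", "is_ntc"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"library table missing columns: {missing}")

        dup_ids = df.loc[df["sgrna_id"].duplicated(keep=False), "sgrna_id"]
        if len(dup_ids):
            raise ValueError(
                "duplicate sgrna_id values: " + ", ".join(sorted(dup_ids.unique()))
            )
        dup_mask = df["protospacer"].duplicated(keep=False)
        if dup_mask.any():
            offenders = df.loc[dup_mask].sort_values("protospacer")
            pairs = "; ".join(
                f"{proto}: {', '.join(sub['sgrna_id'])}"
                for proto, sub in offenders.groupby("protospacer")
            )
            raise ValueError(f"duplicate protospacers shared by sgRNAs — {pairs}")

        bad = [
            sid
            for sid, proto in zip(df["sgrna_id"], df["protospacer"])
            if not proto or not set(proto) <= _VALID_BASES
        ]
        if bad:
            raise ValueError(
                "protospacers with non-ACGT characters (or empty) for: "
                + ", ".join(bad)
            )

        ntc_groups = set(df.loc[df["is_ntc"], "gene_group"])
        targeting_groups = set(df.loc[~df["is_ntc"], "gene_group"])
        shared = ntc_groups & targeting_groups
        if shared:
            raise ValueError(
                "gene groups used by both targeting and non-targeting entries: "
                + ", ".join(sorted(shared))
            )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_ntc(self) -> int:
        return int(self.entries["is_ntc"].sum())

    @property
    def ntc_ids(self) -> list[str]:
        return list(self.entries.loc[self.entries["is_ntc"], "sgrna_id"])

    @property
    def ntc_groups(self) -> set[str]:
        return set(self.entries.loc[self.entries["is_ntc"], "gene_group"])

    @property
    def gene_groups(self) -> list[str]:
        """Targeting gene groups (NTC groups excluded), in library order."""
        sub = self.entries.loc[~self.entries["is_ntc"], "gene_group"]
        return list(dict.fromkeys(sub))

    def protospacer_map(self) -> dict[str, str]:
        """protospacer -> sgrna_id (protospacers are unique by invariant)."""
        return dict(zip(self.entries["protospacer"], self.entries["sgrna_id"]))

    def summary(self) -> dict[str, int]:
        return {
            "entries": len(self),
            "gene_groups": len(self.gene_groups),
            "ntcs": self.n_ntc,
        }

    def to_tsv(self, path: str | Path) -> None:
        out = self.entries.copy()
        out["is_ntc"] = out["is_ntc"].astype(int)
        out.to_csv(path, sep="\t", index=False)


def parse_library(
    source,
    *,
    id_col: str = "sgrna_id",
    gene_col: str = "gene_group",
    protospacer_col: str = "protospacer",
    ntc_col: str = "is_ntc",
    sep: str | None = None,
) -> LibraryTable:
    """Read a delimited sgRNA reference table into a :class:`LibraryTable`.

    ``sep=None`` infers tab vs comma from the file extension (default tab).
    The NTC column accepts booleans, 0/1, or true/false strings.
    """
    if sep is None:
        name = str(source)
        sep = "," if name.endswith(".csv") else "\t"
    df = pd.read_csv(source, sep=sep, dtype=str)
    missing = [c for c in (id_col, gene_col, protospacer_col, ntc_col) if c not in df.columns]
    if missing:
        raise ValueError(
            f"reference table missing columns {missing}; found {list(df.columns)}"
        )
    ntc = (
        df[ntc_col]
        .astype(str)
        .str.strip()
        .str.lower()
        .map({"1": True, "true": True, "0": False, "false": False})
    )
    if ntc.isna().any():
        bad = df.loc[ntc.isna(), ntc_col].unique()[:5]
        raise ValueError(f"unrecognized NTC indicator values: {list(bad)}")
    table = pd.DataFrame(
        {
            "sgrna_id": df[id_col].astype(str),
            "gene_group": df[gene_col].astype(str),
            "protospacer": df[protospacer_col].astype(str).str.upper(),
            "is_ntc": ntc.astype(bool),
        }
    )
    return LibraryTable(table)


@dataclass
class ReadCounts:
    """One count-matrix column: per-sgRNA assignments plus reject tallies."""

    counts: pd.Series  # index sgrna_id, int
    unassigned: int
    ambiguous: int

    @property
    def total(self) -> int:
        return int(self.counts.sum()) + self.unassigned + self.ambiguous


def _iter_fastq(source) -> Iterator[str]:
    """Yield read sequences from a FASTQ(.gz) path or an iterable of strings."""
    if isinstance(source, (str, Path)):
        import pysam

        with pysam.FastxFile(str(source)) as fh:
            i = 0
            while True:
                try:
                    rec = next(fh)
                except StopIteration:
                    break
                except Exception as exc:
                    raise ValueError(
                        f"malformed FASTQ record at index {i}: {exc}"
                    ) from exc
                seq = rec.sequence
                if not seq or (rec.quality is not None and len(rec.quality) != len(seq)):
                    raise ValueError(f"malformed FASTQ record at index {i}")
                yield seq
                i += 1
    else:
        yield from source


def count_reads(
    reads,
    library: LibraryTable,
    orientation: str = "forward",
) -> ReadCounts:
    """Count reads by exact protospacer substring matching.

    ``reads`` is a FASTQ(.gz) path or an iterable of read sequences.
    ``orientation="both"`` additionally scans each read's reverse complement.
    """
    if orientation not in ("forward", "both"):
        raise ValueError("orientation must be 'forward' or 'both'")
    proto_to_id = library.protospacer_map()
    protos = set(proto_to_id)
    lengths = sorted({len(p) for p in protos})

    counts: dict[str, int] = dict.fromkeys(library.entries["sgrna_id"], 0)
    unassigned = 0
    ambiguous = 0
    n_reads = 0

    for seq in _iter_fastq(reads):
        n_reads += 1
        seq = seq.upper()
        views = [seq] if orientation == "forward" else [seq, reverse_complement(seq)]
        hits: set[str] = set()
        for view in views:
            for L in lengths:
                span = len(view) - L + 1
                if span > 0:
                    hits |= protos & {view[i : i + L] for i in range(span)}
        if len(hits) == 1:
            counts[proto_to_id[hits.pop()]] += 1
        elif not hits:
            unassigned += 1
        else:
            ambiguous += 1

    if n_reads == 0:
        warnings.warn("empty FASTQ input: emitting all-zero counts", stacklevel=2)

    series = pd.Series(counts, name="count", dtype=int)
    series.index.name = "sgrna_id"
    return ReadCounts(counts=series, unassigned=unassigned, ambiguous=ambiguous)


@dataclass
class CountMatrix:
    """Integer sgRNA x sample count matrix with sample roles.

    ``counts`` is indexed by sgrna_id with one integer column per sample;
    ``gene_group`` aligns with the index; ``sample_role`` maps each sample
    to ``"control"`` (AAV input library) or ``"treatment"`` (per-mouse
    episome counts); ``mouse_id`` groups treatment samples by animal.
    """

    counts: pd.DataFrame
    gene_group: pd.Series
    sample_role: dict[str, str]
    mouse_id: dict[str, str] = field(default_factory=dict)
    unassigned: dict[str, int] = field(default_factory=dict)
    ambiguous: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.gene_group.index):
            self.gene_group = self.gene_group.reindex(self.counts.index)
            if self.gene_group.isna().any():
                raise ValueError("gene_group missing entries for some sgRNAs")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        unknown = set(self.counts.columns) - set(self.sample_role)
        if unknown:
            raise ValueError(f"samples without a role: {sorted(unknown)}")
        bad_roles = {
            s: r for s, r in self.sample_role.items() if r not in (CONTROL, TREATMENT)
        }
        if bad_roles:
            raise ValueError(f"invalid sample roles: {bad_roles}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.samples if self.sample_role[s] == CONTROL]

    @property
    def treatment_samples(self) -> list[str]:
        return [s for s in self.samples if self.sample_role[s] == TREATMENT]

    @property
    def mice(self) -> list[str]:
        """Distinct mouse ids over treatment samples, in column order."""
        seen: dict[str, None] = {}
        for s in self.treatment_samples:
            seen.setdefault(self.mouse_id.get(s, s), None)
        return list(seen)

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        samples = [s for s in self.samples if s in set(samples)]  # keep order
        return CountMatrix(
            counts=self.counts[samples].copy(),
            gene_group=self.gene_group.copy(),
            sample_role={s: self.sample_role[s] for s in samples},
            mouse_id={s: m for s, m in self.mouse_id.items() if s in set(samples)},
            unassigned={s: v for s, v in self.unassigned.items() if s in set(samples)},
            ambiguous={s: v for s, v in self.ambiguous.items() if s in set(samples)},
        )

    def subset_sgrnas(self, sgrna_ids: Sequence[str]) -> "CountMatrix":
        keep = self.counts.index.intersection(sgrna_ids)
        keep = [i for i in self.counts.index if i in set(keep)]
        return CountMatrix(
            counts=self.counts.loc[keep].copy(),
            gene_group=self.gene_group.loc[keep].copy(),
            sample_role=dict(self.sample_role),
            mouse_id=dict(self.mouse_id),
            unassigned=dict(self.unassigned),
            ambiguous=dict(self.ambiguous),
        )

    def add_column(self, sample: str, column: ReadCounts, role: str, mouse: str | None = None) -> None:
        self.counts[sample] = column.counts.reindex(self.counts.index).fillna(0).astype(int)
        self.sample_role[sample] = role
        if mouse is not None:
            self.mouse_id[sample] = mouse
        self.unassigned[sample] = column.unassigned
        self.ambiguous[sample] = column.ambiguous

    @classmethod
    def empty(cls, library: LibraryTable) -> "CountMatrix":
        idx = pd.Index(library.entries["sgrna_id"], name="sgrna_id")
        return cls(
            counts=pd.DataFrame(index=idx),
            gene_group=pd.Series(
                library.entries["gene_group"].to_numpy(), index=idx, name="gene_group"
            ),
            sample_role={},
        )

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "gene_group", self.gene_group)
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        sample_role: Mapping[str, str],
        mouse_id: Mapping[str, str] | None = None,
    ) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        gene_group = df.pop("gene_group")
        samples = [c for c in df.columns if c in sample_role]
        dropped = [c for c in df.columns if c not in sample_role]
        if dropped:
            warnings.warn(f"samples without a role in the sample sheet ignored: {dropped}")
        return cls(
            counts=df[samples].astype(int),
            gene_group=gene_group.astype(str),
            sample_role={s: sample_role[s] for s in samples},
            mouse_id=dict(mouse_id or {}),
        )


def read_sample_sheet(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a sample sheet TSV (columns: sample, role[, mouse]).

    Returns (sample -> role, sample -> mouse id). Treatment samples without
    an explicit mouse id use the sample name as their mouse id.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "role"):
        if col not in df.columns:
            raise ValueError(f"sample sheet missing required column '{col}'")
    roles = dict(zip(df["sample"], df["role"].str.strip().str.lower()))
    bad = {s: r for s, r in roles.items() if r not in (CONTROL, TREATMENT)}
    if bad:
        raise ValueError(f"sample sheet roles must be control/treatment, got: {bad}")
    if "mouse" in df.columns:
        mice = {
            s: (m if isinstance(m, str) and m else s)
            for s, m in zip(df["sample"], df["mouse"])
        }
    else:
        mice = {s: s for s in df["sample"]}
    mice = {s: m for s, m in mice.items() if roles[s] == TREATMENT}
    return roles, mice
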