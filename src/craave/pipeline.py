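"""End-to-end screen runs: count -> test -> aggregate -> (optional) bootstrap.

A run is described by a :class:`RunConfig` (parsed from a plain
``key = value`` config file with CLI overrides; precedence CLI > file >
defaults). Every stage persists its table as TSV in the output directory
and the effective parameters are echoed to ``manifest.json``, so a run is
reproducible from the manifest alone.
"""

from __future__ import annotations

import json
import logging
import sys
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import bootstrap_screen, derive_amalgam_seed
from .geopagg import GeneResults, aggregate_genes
from .library import (
    CountMatrix,
    LibraryTable,
    count_reads,
    parse_library,
    read_sample_sheet,
)
from .sgrna_stats import SgrnaResult, analyze_sgrnas

__all__ = ["RunConfig", "run_screen", "per_mouse_results", "write_sgrna_table"]

logger = logging.getLogger("craave")

FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    library: str = ""
    counts: str = ""
    fastq: dict = field(default_factory=dict)  # sample -> fastq path
    sample_sheet: str = ""
    out_dir: str = "craave_run"
    orientation: str = "forward"
    min_control_reads: int = 100
    pseudocount: float = 1.0
    weight_scheme: str = "uniform"
    fdr_threshold: float = 0.1
    amalgam_factor: int = 1
    gamma_variant: str = "product"
    ntc_group: str = "non-targeting"
    seed: int = 0
    run_bootstrap: bool = False
    bootstrap_sizes: str = ""  # "1:N" or comma list; empty = 1..N
    bootstrap_reps: int = 50

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Parse a ``key = value`` config file; ``#`` starts a comment."""
        raw: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (part.strip() for part in line.split("=", 1))
            raw[key] = val
        known = {f.name: f.type for f in fields(cls)}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        defaults = cls()
        for key, val in raw.items():
            current = getattr(defaults, key)
            if isinstance(current, bool):
                kwargs[key] = val.strip().lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                kwargs[key] = int(val)
            elif isinstance(current, float):
                kwargs[key] = float(val)
            elif isinstance(current, dict):
                kwargs[key] = dict(
                    pair.split(":", 1) for pair in val.split(",") if pair
                )
            else:
                kwargs[key] = val
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)

    def validate(self) -> None:
        if not self.sample_sheet:
            raise ValueError("config missing required field 'sample_sheet'")
        if not self.counts and not (self.fastq and self.library):
            raise ValueError(
                "config needs either 'counts' or both 'fastq' and 'library'"
            )


def write_sgrna_table(result: SgrnaResult, path: str | Path) -> None:
    result.table.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def _load_counts(config: RunConfig) -> CountMatrix:
    roles, mice = read_sample_sheet(config.sample_sheet)
    if config.counts:
        return CountMatrix.from_tsv(config.counts, roles, mice)
    library = parse_library(config.library)
    matrix = CountMatrix.empty(library)
    for sample, fastq in config.fastq.items():
        if sample not in roles:
            raise ValueError(f"FASTQ sample {sample!r} missing from the sample sheet")
        col = count_reads(fastq, library, orientation=config.orientation)
        matrix.add_column(sample, col, roles[sample], mice.get(sample))
        logger.info(
            "counted %s: %d assigned, %d unassigned, %d ambiguous",
            sample, int(col.counts.sum()), col.unassigned, col.ambiguous,
        )
    return matrix


def run_screen(config: RunConfig) -> GeneResults:
    """Execute the full pipeline described by ``config``.

    Writes counts.tsv (when counting from FASTQ), sgrna_stats.tsv,
    genes.tsv, amalgam_diagnostics.tsv and manifest.json under
    ``config.out_dir``; returns the gene-level results.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logger.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers[:-1]):
        logger.addHandler(logging.StreamHandler(sys.stderr))
    logger.setLevel(logging.INFO)

    try:
        counts = _load_counts(config)
        logger.info(
            "count matrix: %d sgRNAs x %d samples (%d control, %d treatment)",
            len(counts.counts), len(counts.samples),
            len(counts.control_samples), len(counts.treatment_samples),
        )
        if config.fastq:
            counts.to_tsv(out / "counts.tsv")

        sg = analyze_sgrnas(
            counts,
            min_control_reads=config.min_control_reads,
            pseudocount=config.pseudocount,
            weight_scheme=config.weight_scheme,
        )
        logger.info(
            "sgRNA stage: %d guides dropped by coverage filter, %d tested "
            "(dispersion: slope %.4f, intercept %.4f)",
            len(sg.dropped), len(sg.table), sg.fit.slope, sg.fit.intercept,
        )
        write_sgrna_table(sg, out / "sgrna_stats.tsv")

        amalgam_seed = derive_amalgam_seed(config.seed)
        genes = aggregate_genes(
            sg.table,
            ntc_groups=config.ntc_group,
            seed=amalgam_seed,
            amalgam_factor=config.amalgam_factor,
            gamma_variant=config.gamma_variant,
            fdr_threshold=config.fdr_threshold,
        )
        n_hits = int(genes.genes["is_hit"].sum())
        logger.info(
            "geopagg: %d genes scored, %d amalgam genes, %d hits at FDR < %g",
            len(genes.genes), genes.meta["n_amalgam"], n_hits, config.fdr_threshold,
        )
        genes.genes.to_csv(out / "genes.tsv", sep="\t", float_format=FLOAT_FORMAT)
        genes.diagnostics.to_csv(
            out / "amalgam_diagnostics.tsv", sep="\t", index=False,
            float_format=FLOAT_FORMAT,
        )

        manifest = {
            "tool": "craave",
            "version": __version__,
            "config": asdict(config),
            "amalgam_seed": amalgam_seed,
            "n_sgrnas_tested": len(sg.table),
            "n_sgrnas_dropped": len(sg.dropped),
            "n_genes": len(genes.genes),
            "n_hits": n_hits,
        }

        if config.run_bootstrap:
            n_mice = len(counts.mice)
            sizes = _parse_sizes(config.bootstrap_sizes, n_mice)
            report = bootstrap_screen(
                counts,
                sizes=sizes,
                reps=config.bootstrap_reps,
                fdr=config.fdr_threshold,
                seed=config.seed,
                ntc_groups=config.ntc_group,
                amalgam_factor=config.amalgam_factor,
                gamma_variant=config.gamma_variant,
                min_control_reads=config.min_control_reads,
                pseudocount=config.pseudocount,
                weight_scheme=config.weight_scheme,
            )
            report.overlaps.to_csv(
                out / "bootstrap_overlap.tsv", sep="\t", index=False,
                float_format=FLOAT_FORMAT,
            )
            report.recovery.to_csv(
                out / "bootstrap_recovery.tsv", sep="\t", index=False,
                float_format=FLOAT_FORMAT,
            )
            manifest["bootstrap"] = {
                "sizes": report.sizes,
                "reps": report.reps,
                "full_hits": report.full_hits,
            }

        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return genes
    except Exception as exc:  # annotate which stage failed
        logger.error("run failed: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _parse_sizes(spec: str, n_mice: int) -> list[int]:
    if not spec:
        return list(range(1, n_mice + 1))
    if ":" in spec:
        lo, hi = spec.split(":", 1)
        hi = n_mice if hi in ("", "N") else int(hi)
        return list(range(int(lo), hi + 1))
    return [int(s) for s in spec.split(",")]


def per_mouse_results(
    counts: CountMatrix,
    min_control_reads: int = 100,
    pseudocount: float = 1.0,
    weight_scheme: str = "uniform",
    ntc_groups="non-targeting",
    seed: int = 0,
    amalgam_factor: int = 1,
    gamma_variant: str = "product",
    fdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """Gene phenotype matrix with one column per mouse.

    Each mouse's treatment columns are analyzed alone against all control
    columns with the same parameters, so a single-mouse run is identical
    to a cohort analysis of that mouse. Returns a gene x mouse matrix of
    aggregated phenotypes phi_i.
    """
    if not counts.treatment_samples:
        raise ValueError("no treatment samples")
    amalgam_seed = derive_amalgam_seed(seed)
    columns = {}
    for mouse in counts.mice:
        cols = counts.control_samples + [
            s for s in counts.treatment_samples
            if counts.mouse_id.get(s, s) == mouse
        ]
        subset = counts.subset_samples(cols)
        mouse_total = subset.counts[subset.treatment_samples].to_numpy().sum()
        if mouse_total == 0:
            # degenerate: nothing recovered from this mouse — report the
            # pseudocount-floor phenotype per gene rather than failing
            warnings.warn(
                f"mouse {mouse!r} has zero treatment counts; phenotypes sit at "
                "the pseudocount floor",
                stacklevel=2,
            )
            from .sgrna_stats import filter_low_coverage, median_normalize

            kept, _ = filter_low_coverage(subset, min_control_reads)
            norm = median_normalize(kept.counts[kept.control_samples])
            mu_c = norm.values.mean(axis=1)
            phi_guide = np.log2(pseudocount / (mu_c + pseudocount))
            ntc = (
                {ntc_groups} if isinstance(ntc_groups, str) else set(ntc_groups)
            )
            real = ~kept.gene_group.isin(ntc)
            columns[mouse] = (
                phi_guide[real].groupby(kept.gene_group[real]).mean()
            )
            continue
        sg = analyze_sgrnas(
            subset,
            min_control_reads=min_control_reads,
            pseudocount=pseudocount,
            weight_scheme=weight_scheme,
        )
        genes = aggregate_genes(
            sg.table,
            ntc_groups=ntc_groups,
            seed=amalgam_seed,
            amalgam_factor=amalgam_factor,
            gamma_variant=gamma_variant,
            fdr_threshold=fdr_threshold,
        )
        columns[mouse] = genes.genes["phi"]
    matrix = pd.DataFrame(columns)
    matrix.index.name = "gene_group"
    return matrix
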