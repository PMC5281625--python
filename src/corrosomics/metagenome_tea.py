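"""Downstream arithmetic on metagenome annotation products.

Works from three text inputs produced upstream of this package (read
mapping, assembly, binning, and gene annotation are out of scope): a
gene/ORF read-count table with metagenome sizes, and a genome-bin table
carrying per-sample mean coverage and gene annotations.

Provides hits-per-million-reads normalization, fold comparisons of gene
families between sample groups, presence calling of terminal-electron-
acceptor (TEA) pathways on genome bins, and the coverage-based estimate of
the fraction of community cells carrying a pathway: a bin's mean coverage
times its length is the number of bases recruited to it, and dividing by
the total bases sequenced gives its read share, a proxy for its cell
fraction in the community.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GenomeBin",
    "PathwayDefinition",
    "PathwayCall",
    "CellFraction",
    "FoldResult",
    "DEFAULT_PATHWAYS",
    "per_million",
    "fold_comparison",
    "call_pathway",
    "cell_fraction",
    "read_bin_table",
    "write_bin_table",
    "read_gene_counts",
    "read_metagenome_sizes",
    "read_pathway_definitions",
    "write_pathway_definitions",
]


@dataclass
class GenomeBin:
    """A reconstructed genome scaffold (bin) with coverage and annotations."""

    bin_id: str
    site: str
    contig_count: int
    total_length: int  # bp
    coverage: dict[str, float] = field(default_factory=dict)  # sample -> mean depth (x)
    gene_annotations: frozenset[str] = frozenset()
    recruitment_label: str = ""

    def __post_init__(self) -> None:
        if self.total_length <= 0:
            raise ValueError(f"bin {self.bin_id}: total_length must be positive")
        if any(v < 0 for v in self.coverage.values()):
            raise ValueError(f"bin {self.bin_id}: coverage must be non-negative")
        self.gene_annotations = frozenset(self.gene_annotations)


@dataclass(frozen=True)
class PathwayDefinition:
    """A pathway is present when every required group is hit by at least one
    of its alternative genes (groups are AND-ed, genes within a group OR-ed)."""

    pathway_id: str
    required_groups: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.required_groups or any(not g for g in self.required_groups):
            raise ValueError(f"{self.pathway_id}: need at least one non-empty gene group")


def _definition(pathway_id: str, groups: Sequence[Iterable[str]]) -> PathwayDefinition:
    return PathwayDefinition(pathway_id, tuple(frozenset(g) for g in groups))


#: Default marker-gene definitions for the TEA and hydrocarbon pathways.
#: These are configuration, not fixed science: override via a YAML file
#: (pathway_id -> list of alternative-gene lists) for other marker choices.
DEFAULT_PATHWAYS: dict[str, PathwayDefinition] = {
    "denitrification": _definition(
        "denitrification", [["narG", "napA"], ["nirS", "nirK"], ["norB"], ["nosZ"]]
    ),
    "sulfate_reduction": _definition("sulfate_reduction", [["dsrA"], ["dsrB"]]),
    "methanogenesis": _definition("methanogenesis", [["mcrA"]]),
    "aerobic_hydrocarbon": _definition(
        "aerobic_hydrocarbon", [["alkB", "xylM", "todC1", "phnA1", "cdo"]]
    ),
    "anaerobic_hydrocarbon": _definition(
        "anaerobic_hydrocarbon", [["assA", "bssA", "nmsA"]]
    ),
}


@dataclass(frozen=True)
class PathwayCall:
    bin_id: str
    pathway_id: str
    present: bool
    satisfied_groups: tuple[frozenset[str], ...]
    missing_groups: tuple[frozenset[str], ...]


@dataclass
class CellFraction:
    pathway_id: str
    sample: str
    percent: float
    per_bin_percent: dict[str, float]
    total_bases: float


@dataclass
class FoldResult:
    value: "float | dict[str, float]"
    infinite: bool
    aggregate: str


def per_million(counts: pd.DataFrame, total_reads: Mapping[str, float]) -> pd.DataFrame:
    """Normalize a gene x sample read-count table to hits per million reads."""
    out = counts.astype(float).copy()
    for sample in out.columns:
        if sample not in total_reads:
            raise KeyError(f"no metagenome size for sample {sample!r}")
        size = float(total_reads[sample])
        if size <= 0:
            raise ValueError(f"metagenome size for {sample!r} must be positive")
        out[sample] = out[sample] / size * 1e6
    return out


def fold_comparison(
    freqs: pd.DataFrame,
    gene_family: Iterable[str],
    group_a: Sequence[str],
    group_b: Sequence[str],
    aggregate: str = "mean",
) -> FoldResult:
    """Ratio of a gene family's per-million frequency between sample groups.

    ``aggregate='mean'`` compares group means of the family totals;
    ``'per-sample'`` pairs samples positionally and returns one ratio per
    pair.  A zero denominator yields ``inf`` with the infinite flag set.
    """
    genes = [g for g in gene_family]
    missing = [g for g in genes if g not in freqs.index]
    if missing:
        raise KeyError(f"genes absent from the frequency table: {missing}")
    if not genes:
        raise ValueError("empty gene family")
    totals = freqs.loc[genes].sum(axis=0)
    if aggregate == "mean":
        num = float(totals[list(group_a)].mean())
        den = float(totals[list(group_b)].mean())
        value = math.inf if den == 0 else num / den
        return FoldResult(value=value, infinite=den == 0, aggregate="mean")
    if aggregate == "per-sample":
        if len(group_a) != len(group_b):
            raise ValueError("per-sample comparison needs equally sized groups")
        ratios: dict[str, float] = {}
        infinite = False
        for a, b in zip(group_a, group_b):
            den = float(totals[b])
            if den == 0:
                ratios[f"{a}/{b}"] = math.inf
                infinite = True
            else:
                ratios[f"{a}/{b}"] = float(totals[a]) / den
        return FoldResult(value=ratios, infinite=infinite, aggregate="per-sample")
    raise ValueError("aggregate must be 'mean' or 'per-sample'")


def call_pathway(genome_bin: GenomeBin, definition: PathwayDefinition) -> PathwayCall:
    """Present iff every required gene group intersects the bin's annotations."""
    satisfied = tuple(g for g in definition.required_groups if g & genome_bin.gene_annotations)
    missing = tuple(g for g in definition.required_groups if not (g & genome_bin.gene_annotations))
    return PathwayCall(
        bin_id=genome_bin.bin_id,
        pathway_id=definition.pathway_id,
        present=not missing,
        satisfied_groups=satisfied,
        missing_groups=missing,
    )


def cell_fraction(
    bins: Sequence[GenomeBin],
    definition: PathwayDefinition,
    sample: str,
    total_bases: float,
) -> CellFraction:
    """Percent of the community estimated to carry a pathway in one sample.

    Sums coverage x length (bases recruited) over pathway-positive bins and
    divides by the total bases sequenced for the sample.  Because binning
    is rarely complete, fractions across pathways need not reach 100%.
    """
    if total_bases <= 0:
        raise ValueError("total_bases must be positive")
    per_bin: dict[str, float] = {}
    for b in bins:
        if sample not in b.coverage:
            raise KeyError(f"bin {b.bin_id} has no coverage for sample {sample!r}")
        if call_pathway(b, definition).present:
            per_bin[b.bin_id] = b.coverage[sample] * b.total_length / total_bases * 100.0
    return CellFraction(
        pathway_id=definition.pathway_id,
        sample=sample,
        percent=float(sum(per_bin.values())),
        per_bin_percent=per_bin,
        total_bases=float(total_bases),
    )


# ---------------------------------------------------------------------------
# delimited-text interfaces

_BIN_FIXED_COLUMNS = ["bin_id", "site", "contig_count", "total_length_bp", "gene_annotations", "recruitment_label"]


def write_bin_table(bins: Sequence[GenomeBin], path) -> None:
    samples = sorted({s for b in bins for s in b.coverage})
    rows = []
    for b in bins:
        row = {
            "bin_id": b.bin_id,
            "site": b.site,
            "contig_count": b.contig_count,
            "total_length_bp": b.total_length,
            "gene_annotations": ";".join(sorted(b.gene_annotations)),
            "recruitment_label": b.recruitment_label,
        }
        for s in samples:
            row[f"coverage_{s}"] = b.coverage.get(s, "")
        rows.append(row)
    columns = _BIN_FIXED_COLUMNS[:4] + [f"coverage_{s}" for s in samples] + _BIN_FIXED_COLUMNS[4:]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def read_bin_table(path) -> list[GenomeBin]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_BIN_FIXED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    coverage_cols = [c for c in df.columns if c.startswith("coverage_")]
    bins = []
    for _, row in df.iterrows():
        coverage = {
            c[len("coverage_"):]: float(row[c]) for c in coverage_cols if pd.notna(row[c]) and row[c] != ""
        }
        genes = row["gene_annotations"]
        annotations = frozenset(g for g in str(genes).split(";") if g) if pd.notna(genes) else frozenset()
        bins.append(
            GenomeBin(
                bin_id=str(row["bin_id"]),
                site=str(row["site"]),
                contig_count=int(row["contig_count"]),
                total_length=int(row["total_length_bp"]),
                coverage=coverage,
                gene_annotations=annotations,
                recruitment_label="" if pd.isna(row["recruitment_label"]) else str(row["recruitment_label"]),
            )
        )
    return bins


def read_gene_counts(path) -> pd.DataFrame:
    """Read a long gene-count table (gene, sample, count) into gene x sample."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "sample", "count"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    wide = df.pivot_table(index="gene", columns="sample", values="count", aggfunc="sum", fill_value=0)
    wide.columns.name = None
    return wide


def read_metagenome_sizes(path) -> pd.DataFrame:
    """Read a sizes table: sample, total_reads, total_bases (indexed by sample)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "total_reads", "total_bases"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df.set_index("sample")


def read_pathway_definitions(path) -> dict[str, PathwayDefinition]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping pathway_id -> list of gene groups")
    return {pid: _definition(pid, groups) for pid, groups in raw.items()}


def write_pathway_definitions(definitions: Mapping[str, PathwayDefinition], path) -> None:
    raw = {pid: [sorted(g) for g in d.required_groups] for pid, d in definitions.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)
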