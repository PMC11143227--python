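"""Marker-gene quantification: genome equivalents, RPKG, pathway and taxon
abundances, diversity indices, coefficient of variation.

Gene abundance is normalized as reads per kilobase per genome equivalent
(RPKG): the genome equivalent of a metagenome is its library size in bp
divided by its average genome size (AGS, bp), and

    RPKG = mapped reads / (gene length [kbp] * genome equivalent)

which makes abundances comparable across libraries of different depth and
community genome size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MarkerQuantTable",
    "genome_equivalents",
    "rpkg",
    "quantify",
    "aggregate_pathways",
    "taxon_relative_abundance",
    "shannon_richness",
    "coefficient_of_variation",
]


@dataclass
class MarkerQuantTable:
    """Per-sample mapped-read counts plus the library metadata RPKG needs.

    ``reads``: integer frame (sample x gene). ``library_size_bp`` and
    ``ags_bp``: per-sample series aligned to ``reads.index``. Mapped reads may
    exceed no bound relative to library size - the catalog is a reduced gene
    set, not the whole library.
    """

    reads: pd.DataFrame
    library_size_bp: pd.Series
    ags_bp: pd.Series

    def __post_init__(self) -> None:
        if (self.reads.to_numpy() < 0).any():
            raise ValueError("mapped reads must be non-negative")
        for s in (self.library_size_bp, self.ags_bp):
            if not s.index.equals(self.reads.index):
                raise ValueError("metadata index must match reads index")
            if (s <= 0).any():
                raise ValueError("library_size_bp and ags_bp must be positive")

    def to_frame(self) -> pd.DataFrame:
        """Single wide table (metadata columns first) for TSV round-trips."""
        return pd.concat([self.library_size_bp, self.ags_bp, self.reads], axis=1)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerQuantTable":
        meta = ["library_size_bp", "ags_bp"]
        missing = [c for c in meta if c not in df.columns]
        if missing:
            raise ValueError(f"missing metadata column(s): {missing}")
        reads = df.drop(columns=meta).astype(np.int64)
        reads.index.name = "sample_id"
        reads.columns.name = "gene_id"
        lib = df["library_size_bp"].astype(np.int64)
        ags = df["ags_bp"].astype(float)
        lib.index.name = ags.index.name = "sample_id"
        return cls(reads=reads, library_size_bp=lib, ags_bp=ags)


def genome_equivalents(library_size_bp, ags_bp):
    """Effective number of genomes sequenced: library size (bp) / AGS (bp)."""
    lib = np.asarray(library_size_bp, dtype=float)
    ags = np.asarray(ags_bp, dtype=float)
    if np.any(lib <= 0) or np.any(ags <= 0):
        raise ValueError("library size and AGS must be positive")
    out = lib / ags
    return float(out) if out.ndim == 0 else out


def rpkg(mapped_reads, gene_length_kbp, genome_equivalent):
    """Reads per kilobase per genome equivalent."""
    reads = np.asarray(mapped_reads, dtype=float)
    length = np.asarray(gene_length_kbp, dtype=float)
    ge = np.asarray(genome_equivalent, dtype=float)
    if np.any(length <= 0):
        raise ValueError("gene length must be positive")
    if np.any(ge <= 0):
        raise ValueError("genome equivalent must be positive")
    if np.any(reads < 0):
        raise ValueError("mapped reads must be non-negative")
    out = reads / (length * ge)
    return float(out) if out.ndim == 0 else out


def quantify(table: MarkerQuantTable, catalog: pd.DataFrame) -> pd.DataFrame:
    """Gene-level RPKG profile (sample x gene) from a mapped-read table."""
    missing = set(table.reads.columns) - set(catalog["gene_id"])
    if missing:
        raise ValueError(f"gene(s) absent from catalog: {sorted(missing)[:5]}")
    lengths = catalog.set_index("gene_id")["length_kbp"].reindex(table.reads.columns)
    ge = genome_equivalents(table.library_size_bp, table.ags_bp)
    values = table.reads.to_numpy(dtype=float) / (
        lengths.to_numpy()[None, :] * np.asarray(ge)[:, None]
    )
    return pd.DataFrame(values, index=table.reads.index, columns=table.reads.columns)


def aggregate_pathways(gene_profile: pd.DataFrame, catalog: pd.DataFrame,
                       how: str = "sum") -> pd.DataFrame:
    """Pathway abundance = sum (default) of member-gene RPKG.

    Pathways present in the catalog but without detected genes get 0.
    """
    if how not in ("sum", "mean"):
        raise ValueError("how must be 'sum' or 'mean'")
    cat = catalog.set_index("gene_id")
    missing = set(gene_profile.columns) - set(cat.index)
    if missing:
        raise ValueError(f"gene(s) absent from catalog: {sorted(missing)[:5]}")
    membership = cat["pathway"].reindex(gene_profile.columns)
    grouped = gene_profile.T.groupby(membership).agg(how).T
    all_pathways = pd.Index(pd.unique(catalog["pathway"]), name="pathway")
    return grouped.reindex(columns=all_pathways, fill_value=0.0)


def taxon_relative_abundance(taxon_profile: pd.DataFrame,
                             as_fraction: bool = False) -> pd.DataFrame:
    """Taxon abundance table, optionally renormalized to fractions of the
    per-sample total (defaults to RPKG as-is)."""
    if (taxon_profile.to_numpy() < 0).any():
        raise ValueError("abundances must be non-negative")
    if not as_fraction:
        return taxon_profile.copy()
    totals = taxon_profile.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = taxon_profile.div(totals, axis=0)
    return out.fillna(0.0)


def shannon_richness(taxon_profile: pd.DataFrame) -> pd.DataFrame:
    """Richness (count of taxa with positive abundance) and Shannon index
    (natural log, zero-abundance taxa excluded) per sample."""
    x = taxon_profile.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    richness = (x > 0).sum(axis=1)
    totals = x.sum(axis=1)
    if np.any(totals == 0):
        warnings.warn("all-zero profile(s): Shannon defined as 0")
    shannon = np.zeros(len(x))
    ok = totals > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = x[ok] / totals[ok, None]
        terms = np.where(p > 0, p * np.log(p), 0.0)
    shannon[ok] = -terms.sum(axis=1)
    # clip tiny negative rounding residue on single-taxon profiles
    shannon = np.where(np.abs(shannon) < 1e-15, 0.0, shannon)
    return pd.DataFrame(
        {"richness": richness.astype(int), "shannon": shannon},
        index=taxon_profile.index,
    )


def coefficient_of_variation(values) -> float:
    """Sample standard deviation (n-1 denominator) divided by the mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(x.std(ddof=1) / mean)
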