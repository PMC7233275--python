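"""Packaged reference datasets.

Small text fixtures shipped with the package:

* the eight replicate-by-cluster matrices of the known-haplotype
  discrimination trials, with the originally reported sensitivity /
  specificity / accuracy integers;
* the wild-population table (haplotype counts, coordinates, mountain-range
  groups for eight Cyclopia subternata populations);
* the list of haplotype contrasts that melt clustering failed to separate,
  with their nucleotide-difference classes;
* synthetic stand-in alignments for the two screened chloroplast loci
  (atpI-atpH intergenic spacer, ndhA intron).  The real accession sequences
  are external database records; these stand-ins reproduce the published
  summary structure (561 bp concatenated, ~29% GC, four transversions, one
  transition, one 7 bp indel, star-shaped genealogy) and are labelled
  synthetic in their filenames.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
from Bio import SeqIO

from .discrimination import ReplicateMatrix
from .haplotyping import HaplotypeSet, reduce_indels
from .popgen import PopulationTable

__all__ = [
    "load_population_table",
    "load_discrimination_trials",
    "load_discrimination_reported",
    "load_undiscriminated_contrasts",
    "load_wild_locus",
    "load_wild_haplotypes",
    "WILD_LOCI",
]

WILD_LOCI = ("atpI-atpH", "ndhA")


def _data_path(name: str):
    return resources.files("hrmhap").joinpath("data", name)


def load_population_table() -> PopulationTable:
    """Wild-population haplotype counts, coordinates and range groups."""
    with resources.as_file(_data_path("populations.tsv")) as path:
        return PopulationTable.from_tsv(path)


def load_discrimination_trials() -> dict[str, ReplicateMatrix]:
    """Replicate-by-cluster matrices of the eight primer-pair trials."""
    with resources.as_file(_data_path("discrimination_replicates.tsv")) as path:
        df = pd.read_csv(path, sep="\t")
    out: dict[str, ReplicateMatrix] = {}
    cluster_cols = [c for c in df.columns if c.startswith("c")]
    for pp, sub in df.groupby("primer_pair", sort=False):
        cells = {
            row["haplotype"]: {
                int(c[1:]): int(row[c]) for c in cluster_cols if row[c] > 0
            }
            for _, row in sub.iterrows()
        }
        n = dict(zip(sub["haplotype"], sub["n"].astype(int)))
        out[pp] = ReplicateMatrix(cells, n=n, name=pp)
    return out


def load_discrimination_reported() -> pd.DataFrame:
    """Originally reported integer Sen/Spe/Acc per primer pair and haplotype."""
    with resources.as_file(_data_path("discrimination_reported.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def load_undiscriminated_contrasts() -> pd.DataFrame:
    """Haplotype pairs melt clustering could not separate, by SNP class."""
    with resources.as_file(_data_path("undiscriminated_contrasts.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def load_wild_locus(locus: str) -> HaplotypeSet:
    """Synthetic stand-in alignment for one screened locus.

    Sequences are labelled by the concatenated haplotype (A-E) they belong
    to; loci where two haplotypes share an allele carry identical sequences
    under both labels.
    """
    if locus not in WILD_LOCI:
        raise ValueError(f"unknown locus {locus!r}; choose from {WILD_LOCI}")
    name = f"wild_locus_{locus}_synthetic.fasta"
    with resources.as_file(_data_path(name)) as path:
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return HaplotypeSet(locus=locus, sequences=seqs)


def load_wild_haplotypes(indel_coded: bool = True) -> HaplotypeSet:
    """Concatenated two-locus wild haplotype alignment (561 columns).

    With ``indel_coded=True`` (default) the 7 bp indel is collapsed to a
    single fifth-state column, the convention used for network building,
    distances and AMOVA.
    """
    parts = [load_wild_locus(locus) for locus in WILD_LOCI]
    seqs = {
        label: "".join(p.sequences[label] for p in parts)
        for label in parts[0].labels
    }
    combined = HaplotypeSet(locus="+".join(WILD_LOCI), sequences=seqs)
    return reduce_indels(combined) if indel_coded else combined
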