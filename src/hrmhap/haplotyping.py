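"""Assign verified haplotype identities to screened samples.

Wild-population screening runs every sample in duplicate wells and clusters
melt curves per population.  Clusters are verified by sequencing a minimum
number of member accessions; every sample whose duplicates agree inherits
its cluster's verified haplotype, while samples whose duplicates land in
clusters carrying different verified haplotypes are flagged as conflicts
that require sequencing (no majority vote).  Per-locus calls are then
concatenated - chloroplast loci are inherited in tandem without
recombination, so the concatenated sequence is the analysis unit.

Alignment handling: multi-base indels are collapsed to single columns
("indel coding") so a 7 bp gap counts as one mutational event; the
collapsed column carries a fifth character state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

__all__ = [
    "ClusterVerification",
    "HaplotypeCall",
    "HaplotypeSet",
    "assign_haplotypes",
    "concatenate_loci",
    "reduce_indels",
    "pairwise_differences",
    "sequencing_burden",
]

GAP = "-"
INDEL_STATE = "X"  # fifth character state at a collapsed indel column


@dataclass(frozen=True)
class ClusterVerification:
    """Sequencing-confirmed identity of one (group, cluster) pair."""

    group_id: str
    cluster_label: int
    verified_haplotype: str
    n_sequenced: int = 1

    def __post_init__(self) -> None:
        if self.n_sequenced < 1:
            raise ValueError("n_sequenced must be >= 1")


@dataclass(frozen=True)
class HaplotypeCall:
    sample_id: str
    haplotype: str | None
    status: str  # confirmed | inferred | conflict-needs-sequencing
    population_id: str | None = None

    STATUSES = ("confirmed", "inferred", "conflict-needs-sequencing")

    def __post_init__(self) -> None:
        if self.status not in self.STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


@dataclass(frozen=True)
class HaplotypeSet:
    """Aligned haplotype sequences for one locus (gap character '-')."""

    locus: str
    sequences: dict[str, str]
    indel_coded: bool = False

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment for locus {self.locus}: lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def labels(self) -> list[str]:
        return sorted(self.sequences)


class UnverifiedClusterError(ValueError):
    def __init__(self, clusters: Sequence[tuple[str, int]]):
        self.clusters = list(clusters)
        super().__init__(
            "clusters need sequencing before haplotypes can be assigned: "
            + ", ".join(f"{g}/c{c}" for g, c in self.clusters)
        )


def assign_haplotypes(
    assignments: Iterable,
    verification: Iterable[ClusterVerification],
    duplicates: Mapping[str, Sequence[Hashable]],
    sequenced_samples: Iterable[str] = (),
    overrides: Mapping[str, str] | None = None,
) -> list[HaplotypeCall]:
    """Map samples to verified haplotypes through their duplicate wells.

    ``assignments`` are per-group ClusterAssignment objects; ``duplicates``
    maps sample_id -> its wells (normally two).  ``sequenced_samples`` are
    samples with their own Sanger confirmation (status ``confirmed``);
    ``overrides`` resolve duplicate conflicts with an explicit sequencing
    result.  Output order is sorted by sample id, so the mapping is
    deterministic and independent of input ordering.
    """
    ver = {(v.group_id, v.cluster_label): v.verified_haplotype for v in verification}
    well_cluster: dict[Hashable, tuple[str, int]] = {}
    for assignment in assignments:
        for well, lab in assignment.labels.items():
            well_cluster[well] = (assignment.group_id, lab)

    unverified = sorted(
        {well_cluster[w] for wells in duplicates.values() for w in wells
         if w in well_cluster and well_cluster[w] not in ver}
    )
    if unverified:
        raise UnverifiedClusterError(unverified)

    sequenced = set(sequenced_samples)
    overrides = overrides or {}
    calls = []
    for sample in sorted(duplicates):
        wells = [w for w in duplicates[sample] if w in well_cluster]
        if not wells:
            continue
        groups = {well_cluster[w][0] for w in wells}
        population = groups.pop() if len(groups) == 1 else None
        haps = {ver[well_cluster[w]] for w in wells}
        if len(haps) == 1:
            hap = haps.pop()
            status = "confirmed" if sample in sequenced else "inferred"
            calls.append(HaplotypeCall(sample, hap, status, population))
        elif sample in overrides:
            calls.append(HaplotypeCall(sample, overrides[sample], "confirmed", population))
        else:
            calls.append(HaplotypeCall(sample, None, "conflict-needs-sequencing", population))
    return calls


def concatenate_loci(
    calls: Mapping[str, Sequence[HaplotypeCall]],
    sets: Mapping[str, HaplotypeSet],
) -> tuple[HaplotypeSet, dict[str, str]]:
    """Concatenate per-locus calls and alignments into one dataset.

    Loci concatenate in sorted-name order.  Every sample must carry a call
    at every locus; the concatenated haplotype label of a sample is the
    '+'-joined tuple of its per-locus haplotypes, relabelled to the distinct
    observed combinations.  Returns the concatenated alignment (labels =
    observed combinations) and the per-sample concatenated haplotype.
    """
    loci = sorted(sets)
    if sorted(calls) != loci:
        raise ValueError("calls and haplotype sets must cover the same loci")
    per_locus: dict[str, dict[str, str]] = {}
    samples: set[str] = set()
    for locus in loci:
        per_locus[locus] = {}
        for call in calls[locus]:
            if call.haplotype is not None:
                per_locus[locus][call.sample_id] = call.haplotype
            samples.add(call.sample_id)
    combos: dict[str, str] = {}
    for sample in sorted(samples):
        parts = []
        for locus in loci:
            if sample not in per_locus[locus]:
                raise ValueError(f"sample {sample!r} lacks a resolved call at locus {locus!r}")
            parts.append(per_locus[locus][sample])
        combos[sample] = "+".join(parts)

    observed = sorted(set(combos.values()))
    seqs = {}
    for combo in observed:
        parts = combo.split("+")
        seqs[combo] = "".join(sets[locus].sequences[h] for locus, h in zip(loci, parts))
    concatenated = HaplotypeSet(
        locus="+".join(loci),
        sequences=seqs,
        indel_coded=all(sets[l].indel_coded for l in loci),
    )
    return concatenated, combos


def reduce_indels(hapset: HaplotypeSet) -> HaplotypeSet:
    """Collapse each maximal shared gap run to a single indel-coded column.

    Columns are grouped into maximal runs over which the gap pattern
    (which sequences are gapped) is identical and at least one sequence is
    gapped; each such run becomes one column where gapped sequences carry
    the fifth state and the rest keep their first base of the run.  A 7 bp
    indel therefore contributes exactly one pairwise difference afterwards.
    """
    labels = hapset.labels
    seqs = [hapset.sequences[l] for l in labels]
    length = hapset.length
    out: list[list[str]] = [[] for _ in labels]
    col = 0
    while col < length:
        pattern = tuple(s[col] == GAP for s in seqs)
        if not any(pattern):
            for i, s in enumerate(seqs):
                out[i].append(s[col])
            col += 1
            continue
        run_end = col
        while run_end + 1 < length and tuple(s[run_end + 1] == GAP for s in seqs) == pattern:
            run_end += 1
        for i, s in enumerate(seqs):
            out[i].append(INDEL_STATE if pattern[i] else s[col])
        col = run_end + 1
    return HaplotypeSet(
        locus=hapset.locus,
        sequences={l: "".join(out[i]) for i, l in enumerate(labels)},
        indel_coded=True,
    )


def pairwise_differences(hapset: HaplotypeSet, a: str, b: str) -> int:
    """Number of differing columns between two haplotypes of one set."""
    sa, sb = hapset.sequences[a], hapset.sequences[b]
    return sum(1 for x, y in zip(sa, sb) if x != y)


def sequencing_burden(
    assignments: Iterable,
    duplicates: Mapping[str, Sequence[Hashable]],
    min_per_cluster: int = 3,
) -> tuple[int, int]:
    """Samples requiring sequencing under the verification design.

    Every (group, cluster) requires ``min_per_cluster`` sequenced members
    (all members when the cluster is smaller), plus every duplicate-conflict
    sample.  Returns (n_to_sequence, n_samples).
    """
    well_cluster: dict[Hashable, tuple[str, int]] = {}
    for assignment in assignments:
        for well, lab in assignment.labels.items():
            well_cluster[well] = (assignment.group_id, lab)
    cluster_samples: dict[tuple[str, int], set[str]] = {}
    conflicted: set[str] = set()
    for sample, wells in duplicates.items():
        present = [w for w in wells if w in well_cluster]
        clusters = {well_cluster[w] for w in present}
        if len(clusters) > 1:
            conflicted.add(sample)
        for c in clusters:
            cluster_samples.setdefault(c, set()).add(sample)
    to_sequence: set[str] = set(conflicted)
    for c, members in cluster_samples.items():
        clean = sorted(m for m in members if m not in conflicted)
        to_sequence.update(clean[:min_per_cluster])
    return len(to_sequence), len(duplicates)
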