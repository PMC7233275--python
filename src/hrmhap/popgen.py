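"""Population-genetic analysis of haplotype frequency tables.

Covers the downstream phylogeography workflow for chloroplast haplotype
data: pairwise differentiation (Gst, G''st, Jost's D, Prevosti distance),
great-circle geographic distances, Mantel isolation-by-distance tests,
hierarchical AMOVA with Phi statistics, a statistical-parsimony haplotype
network, and neighbor-joining clustering of populations.

Estimator conventions (all overridable):

* Within- and total gene diversity use small-sample corrections: per pair
  of populations, Hs is the mean of (n/(n-1)) (1 - sum p^2) over the two
  populations; Ht = 1 - sum(pbar^2) + Hs / (2 n~) with pbar the unweighted
  mean frequency and n~ the harmonic mean sample size.
* Gst  = (Ht - Hs) / Ht
* G''st = k (Ht - Hs) / ((k Ht - Hs)(1 - Hs)),  k = 2 for pairwise
* Jost's D = (k/(k-1)) (Ht - Hs) / (1 - Hs)
* Prevosti distance = mean over polymorphic sites of (1/2) sum_a |p1a - p2a|
  on the indel-coded alignment, so a multi-base gap counts once.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import skbio

from .haplotyping import HaplotypeSet, pairwise_differences

__all__ = [
    "PopulationTable",
    "DiversityComponents",
    "DifferentiationMatrix",
    "MantelResult",
    "AmovaResult",
    "SPNetwork",
    "pairwise_differentiation",
    "geo_distances",
    "mantel_ibd",
    "amova",
    "sp_network",
    "parsimony_connection_limit",
    "nj_populations",
]

EARTH_RADIUS_KM = 6371.0088


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

class PopulationTable:
    """Per-population haplotype counts, coordinates and grouping.

    Construct from a DataFrame with columns ``population``, ``latitude``,
    ``longitude``, ``group`` and one integer column per haplotype, or via
    :meth:`from_tsv`.
    """

    META_COLS = ("population", "latitude", "longitude", "group")

    def __init__(self, frame: pd.DataFrame) -> None:
        missing = set(self.META_COLS) - set(frame.columns)
        if missing:
            raise ValueError(f"population table missing columns {sorted(missing)}")
        frame = frame.set_index("population") if frame.index.name != "population" else frame
        hap_cols = [c for c in frame.columns if c not in self.META_COLS]
        counts = frame[hap_cols].fillna(0).astype(int)
        if (counts.values < 0).any():
            raise ValueError("haplotype counts must be non-negative")
        if (counts.sum(axis=1) == 0).any():
            bad = counts.index[counts.sum(axis=1) == 0].tolist()
            raise ValueError(f"populations with zero total count: {bad}")
        lat = frame["latitude"].astype(float)
        lon = frame["longitude"].astype(float)
        if (lat.abs() > 90).any() or (lon.abs() > 180).any():
            raise ValueError("coordinates out of range")
        self.counts = counts
        self.latitude = lat
        self.longitude = lon
        self.group = frame["group"].astype(str)

    @classmethod
    def from_tsv(cls, path_or_buffer) -> "PopulationTable":
        return cls(pd.read_csv(path_or_buffer, sep="\t"))

    @property
    def populations(self) -> list[str]:
        return list(self.counts.index)

    @property
    def haplotypes(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def frequencies(self) -> pd.DataFrame:
        return self.counts.div(self.sizes, axis=0)


@dataclass(frozen=True)
class DiversityComponents:
    hs: float
    ht: float
    k: int

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.hs <= self.ht + 1e-9 <= 1 + 1e-9):
            raise ValueError(f"require 0 <= Hs <= Ht <= 1, got Hs={self.hs}, Ht={self.ht}")


@dataclass(frozen=True)
class DifferentiationMatrix:
    measure: str
    populations: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.populations),) * 2:
            raise ValueError("matrix shape must match population count")
        if not np.allclose(v, v.T):
            raise ValueError("differentiation matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("differentiation matrix must have zero diagonal")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.populations, columns=self.populations)


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    transform: str  # linear | log

    @property
    def r_squared(self) -> float:
        return self.r**2


@dataclass(frozen=True)
class AmovaResult:
    """Hierarchical AMOVA: groups / populations-within-groups / within."""

    components: dict[str, float]   # variance components
    percentages: dict[str, float]  # of total variance
    phi: dict[str, float]          # phi_ct, phi_sc, phi_st
    p_values: dict[str, float]
    df: dict[str, int]
    sums_of_squares: dict[str, float]

    LEVELS = ("among_groups", "among_populations_within_groups", "within_populations")


@dataclass(frozen=True)
class SPNetwork:
    graph: nx.Graph
    connection_limit: int

    @property
    def haplotype_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if not d.get("inferred", False))

    def edge_list(self) -> list[tuple[str, str, int]]:
        return sorted((min(u, v), max(u, v), d["steps"]) for u, v, d in self.graph.edges(data=True))


# ---------------------------------------------------------------------------
# differentiation measures
# ---------------------------------------------------------------------------

def _pair_diversity(c1: np.ndarray, c2: np.ndarray, corrected: bool) -> DiversityComponents:
    n1, n2 = c1.sum(), c2.sum()
    p1, p2 = c1 / n1, c2 / n2
    h1 = 1.0 - float(p1 @ p1)
    h2 = 1.0 - float(p2 @ p2)
    if corrected:
        hs = ((n1 / (n1 - 1)) * h1 + (n2 / (n2 - 1)) * h2) / 2.0
    else:
        hs = (h1 + h2) / 2.0
    pbar = (p1 + p2) / 2.0
    ht = 1.0 - float(pbar @ pbar)
    if corrected:
        n_harm = 2.0 / (1.0 / n1 + 1.0 / n2)
        ht += hs / (2.0 * n_harm)
    hs = min(hs, 1.0)
    ht = max(ht, hs)
    return DiversityComponents(hs=hs, ht=min(ht, 1.0), k=2)


def _gst(div: DiversityComponents) -> float:
    return (div.ht - div.hs) / div.ht if div.ht > 0 else 0.0


def _gpp_st(div: DiversityComponents) -> float:
    k, hs, ht = div.k, div.hs, div.ht
    denom = (k * ht - hs) * (1.0 - hs)
    return k * (ht - hs) / denom if denom > 0 else 0.0


def _jost_d(div: DiversityComponents) -> float:
    k, hs, ht = div.k, div.hs, div.ht
    return (k / (k - 1)) * (ht - hs) / (1.0 - hs) if hs < 1 else 0.0


def _prevosti(
    c1: np.ndarray, c2: np.ndarray, haplotypes: Sequence[str], hapset: HaplotypeSet
) -> float:
    """Mean per-site half absolute frequency difference, indel-coded sites."""
    seqs = [hapset.sequences[h] for h in haplotypes]
    length = len(seqs[0])
    n1, n2 = c1.sum(), c2.sum()
    site_vals = []
    for col in range(length):
        states = [s[col] for s in seqs]
        if len(set(states)) == 1:
            continue
        alleles = sorted(set(states))
        p1 = np.array([sum(c1[i] for i, st in enumerate(states) if st == a) for a in alleles]) / n1
        p2 = np.array([sum(c2[i] for i, st in enumerate(states) if st == a) for a in alleles]) / n2
        site_vals.append(0.5 * float(np.abs(p1 - p2).sum()))
    return float(np.mean(site_vals)) if site_vals else 0.0


_MEASURES: dict[str, Callable[[DiversityComponents], float]] = {
    "gst": _gst,
    "gpp_st": _gpp_st,
    "jost_d": _jost_d,
}


def pairwise_differentiation(
    table: PopulationTable,
    measure: str,
    haplotypes: HaplotypeSet | None = None,
    corrected: bool = True,
) -> DifferentiationMatrix:
    """Pairwise population differentiation matrix for one measure.

    ``measure`` is one of gst, gpp_st, jost_d, prevosti.  Prevosti requires
    the indel-coded haplotype alignment.  ``corrected=False`` switches to
    raw (uncorrected) frequency estimators of Hs and Ht.
    """
    pops = table.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    counts = table.counts.values.astype(float)
    k = len(pops)
    out = np.zeros((k, k))
    if measure == "prevosti":
        if haplotypes is None:
            raise ValueError("prevosti distance requires haplotype sequences")
        if not haplotypes.indel_coded:
            raise ValueError("prevosti distance requires an indel-coded alignment")
        for i in range(k):
            for j in range(i + 1, k):
                out[i, j] = out[j, i] = _prevosti(
                    counts[i], counts[j], table.haplotypes, haplotypes
                )
    elif measure in _MEASURES:
        fn = _MEASURES[measure]
        for i in range(k):
            for j in range(i + 1, k):
                div = _pair_diversity(counts[i], counts[j], corrected)
                out[i, j] = out[j, i] = min(max(fn(div), 0.0), 1.0)
    else:
        raise ValueError(f"unknown measure {measure!r}; choose from "
                         f"{sorted(_MEASURES) + ['prevosti']}")
    return DifferentiationMatrix(measure=measure, populations=tuple(pops), values=out)


# ---------------------------------------------------------------------------
# geography and Mantel tests
# ---------------------------------------------------------------------------

def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance on the mean-radius sphere, in kilometres."""
    la1, la2 = np.radians(lat1), np.radians(lat2)
    dla = la2 - la1
    dlo = np.radians(lon2 - lon1)
    a = np.sin(dla / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin(dlo / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1))))


def geo_distances(
    table: PopulationTable, transform: str = "linear", method: str = "haversine"
) -> pd.DataFrame:
    """Pairwise geographic distance matrix in km (or ln km).

    ``method='euclidean'`` switches to Euclidean distance on raw decimal
    degrees (a convention-sensitivity check, not a recommended metric).
    """
    pops = table.populations
    n = len(pops)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if method == "haversine":
                d = haversine_km(
                    table.latitude.iloc[i], table.longitude.iloc[i],
                    table.latitude.iloc[j], table.longitude.iloc[j],
                )
            elif method == "euclidean":
                d = float(np.hypot(
                    table.latitude.iloc[i] - table.latitude.iloc[j],
                    table.longitude.iloc[i] - table.longitude.iloc[j],
                ))
            else:
                raise ValueError(f"unknown method {method!r}")
            out[i, j] = out[j, i] = d
    if transform == "log":
        off = ~np.eye(n, dtype=bool)
        if np.any(out[off] <= 0):
            raise ValueError("log transform requires distinct coordinates (no zero distances)")
        out[off] = np.log(out[off])
    elif transform != "linear":
        raise ValueError(f"unknown transform {transform!r}")
    return pd.DataFrame(out, index=pops, columns=pops)


def mantel_ibd(
    genetic: DifferentiationMatrix | pd.DataFrame | np.ndarray,
    geographic: pd.DataFrame | np.ndarray,
    n_permutations: int = 9999,
    seed: int | np.random.Generator | None = None,
    transform: str = "linear",
) -> MantelResult:
    """One-sided Mantel test of isolation by distance.

    r is the Pearson correlation of the lower-triangle entries; the p-value
    is (1 + #{permuted r >= observed r}) / (n_permutations + 1) under
    simultaneous row/column permutation of one matrix.
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    G = genetic.values if hasattr(genetic, "values") else np.asarray(genetic, dtype=float)
    D = geographic.values if hasattr(geographic, "values") else np.asarray(geographic, dtype=float)
    if G.shape != D.shape or G.shape[0] != G.shape[1]:
        raise ValueError("matrices must be square and of matching size")
    n = G.shape[0]
    tril = np.tril_indices(n, -1)
    g = G[tril]
    if np.allclose(g, g[0]) or np.allclose(D[tril], D[tril][0]):
        raise ValueError("constant matrix: Mantel correlation undefined")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def corr(perm: np.ndarray) -> float:
        d = D[np.ix_(perm, perm)][tril]
        return float(np.corrcoef(g, d)[0, 1])

    observed = corr(np.arange(n))
    count = 0
    for _ in range(n_permutations):
        if corr(rng.permutation(n)) >= observed - 1e-12:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return MantelResult(r=observed, p_value=p, n_permutations=n_permutations, transform=transform)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def _amova_components(
    counts: np.ndarray, groups_of_pop: np.ndarray, d2: np.ndarray
) -> tuple[dict, dict, dict]:
    """Variance components for one (possibly permuted) configuration.

    counts: populations x haplotypes; d2: squared inter-haplotype distances.
    """
    npop = counts.sum(axis=1)
    N = npop.sum()
    P = len(npop)
    group_ids = sorted(set(groups_of_pop))
    G = len(group_ids)

    def ss(c: np.ndarray) -> float:
        m = c.sum()
        return float(c @ d2 @ c) / (2.0 * m) if m > 0 else 0.0

    ss_total = ss(counts.sum(axis=0))
    ss_within = sum(ss(counts[i]) for i in range(P))
    ss_group = sum(
        ss(counts[[i for i in range(P) if groups_of_pop[i] == g]].sum(axis=0))
        for g in group_ids
    )
    ssd = {
        "among_groups": ss_total - ss_group,
        "among_populations_within_groups": ss_group - ss_within,
        "within_populations": ss_within,
    }
    df = {
        "among_groups": G - 1,
        "among_populations_within_groups": P - G,
        "within_populations": int(N) - P,
    }
    ms = {k: ssd[k] / df[k] if df[k] > 0 else 0.0 for k in ssd}

    group_sizes = {g: sum(npop[i] for i in range(P) if groups_of_pop[i] == g) for g in group_ids}
    sum_sq_within_group = sum(
        sum(npop[i] ** 2 for i in range(P) if groups_of_pop[i] == g) / group_sizes[g]
        for g in group_ids
    )
    n1 = (N - sum_sq_within_group) / df["among_populations_within_groups"]
    n2 = (sum_sq_within_group - (npop**2).sum() / N) / df["among_groups"]
    n3 = (N - sum(s**2 for s in group_sizes.values()) / N) / df["among_groups"]

    sigma_c = ms["within_populations"]
    sigma_b = (ms["among_populations_within_groups"] - sigma_c) / n1
    sigma_a = (ms["among_groups"] - sigma_c - n2 * sigma_b) / n3
    # negative estimated components are reported as zero (usual convention)
    comps = {
        "among_groups": max(sigma_a, 0.0),
        "among_populations_within_groups": max(sigma_b, 0.0),
        "within_populations": max(sigma_c, 0.0),
    }
    return comps, ssd, df


def amova(
    table: PopulationTable,
    haplotypes: HaplotypeSet,
    hierarchy: Mapping[str, str] | None = None,
    n_permutations: int = 999,
    seed: int | np.random.Generator | None = None,
) -> AmovaResult:
    """Hierarchical analysis of molecular variance with Phi statistics.

    Squared inter-haplotype distances are mismatch counts on the
    indel-coded alignment.  ``hierarchy`` maps population -> group and
    defaults to the table's group column.  Permutation p-values use the
    standard scheme per level: Phi_ST permutes individuals among
    populations, Phi_SC permutes individuals among populations within
    groups, Phi_CT permutes whole populations among groups.
    """
    pops = table.populations
    groups = np.array([
        (hierarchy or table.group.to_dict())[p] for p in pops
    ])
    if len(set(groups)) < 2:
        raise ValueError("need >= 2 groups; for a single group run a one-level AMOVA")
    haps = table.haplotypes
    d2 = np.zeros((len(haps), len(haps)))
    for i, a in enumerate(haps):
        for j, b in enumerate(haps):
            if i != j:
                d2[i, j] = pairwise_differences(haplotypes, a, b)

    counts = table.counts.values.astype(float)
    comps, ssd, df = _amova_components(counts, groups, d2)
    sigma_a = comps["among_groups"]
    sigma_b = comps["among_populations_within_groups"]
    sigma_c = comps["within_populations"]
    total = sigma_a + sigma_b + sigma_c
    phi = {
        "phi_ct": sigma_a / total if total > 0 else 0.0,
        "phi_sc": sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) > 0 else 0.0,
        "phi_st": (sigma_a + sigma_b) / total if total > 0 else 0.0,
    }
    pct = {k: 100.0 * comps[k] / total for k in comps}

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hap_of_ind = np.concatenate([
        np.repeat(np.arange(len(haps)), counts[i].astype(int)) for i in range(len(pops))
    ])
    pop_of_ind = np.concatenate([
        np.full(int(counts[i].sum()), i) for i in range(len(pops))
    ])

    def recount(pop_assign: np.ndarray) -> np.ndarray:
        c = np.zeros_like(counts)
        np.add.at(c, (pop_assign, hap_of_ind), 1.0)
        return c

    exceed = {"phi_st": 0, "phi_sc": 0, "phi_ct": 0}
    group_ids = sorted(set(groups))
    for _ in range(n_permutations):
        # Phi_ST: individuals shuffled among all populations
        perm = rng.permutation(len(pop_of_ind))
        comps_p, _, _ = _amova_components(recount(pop_of_ind[perm]), groups, d2)
        tot = sum(comps_p.values())
        st = (comps_p["among_groups"] + comps_p["among_populations_within_groups"]) / tot if tot > 0 else 0.0
        if st >= phi["phi_st"] - 1e-12:
            exceed["phi_st"] += 1
        # Phi_SC: individuals shuffled among populations within their group
        pop_assign = pop_of_ind.copy()
        for g in group_ids:
            mask = np.isin(pop_of_ind, [i for i in range(len(pops)) if groups[i] == g])
            idx = np.where(mask)[0]
            pop_assign[idx] = pop_of_ind[idx[rng.permutation(len(idx))]]
        comps_p, _, _ = _amova_components(recount(pop_assign), groups, d2)
        sb, sc = comps_p["among_populations_within_groups"], comps_p["within_populations"]
        sc_stat = sb / (sb + sc) if (sb + sc) > 0 else 0.0
        if sc_stat >= phi["phi_sc"] - 1e-12:
            exceed["phi_sc"] += 1
        # Phi_CT: whole populations shuffled among groups
        comps_p, _, _ = _amova_components(counts, groups[rng.permutation(len(pops))], d2)
        tot = sum(comps_p.values())
        ct = comps_p["among_groups"] / tot if tot > 0 else 0.0
        if ct >= phi["phi_ct"] - 1e-12:
            exceed["phi_ct"] += 1
    p_values = {k: (1 + v) / (n_permutations + 1) for k, v in exceed.items()}
    return AmovaResult(
        components=comps, percentages=pct, phi=phi, p_values=p_values,
        df=df, sums_of_squares=ssd,
    )


# ---------------------------------------------------------------------------
# statistical parsimony network
# ---------------------------------------------------------------------------

def parsimony_probability(steps: int, alignment_length: int) -> float:
    """Probability that ``steps`` observed changes hit distinct sites.

    Under a uniform placement of changes over the alignment, parsimony
    (no superimposed change at a site) for a pair differing at j sites has
    probability prod_{i=1}^{j-1} (1 - i/L) - a birthday-collision form that
    approximates the classical statistical-parsimony criterion.
    """
    p = 1.0
    for i in range(1, steps):
        p *= max(0.0, 1.0 - i / alignment_length)
    return p


def parsimony_connection_limit(alignment_length: int, confidence: float = 0.95) -> int:
    """Largest step count whose parsimony probability is >= confidence."""
    j = 1
    while parsimony_probability(j + 1, alignment_length) >= confidence:
        j += 1
    return j


def sp_network(
    haplotypes: HaplotypeSet,
    frequencies: Mapping[str, int] | None = None,
    limit: int | None = None,
) -> SPNetwork:
    """Statistical-parsimony haplotype network with inferred intermediates.

    Pairwise mutational steps are mismatch counts on the indel-coded
    alignment.  Edges are added in increasing step order, keeping all
    co-minimal ties, skipping edges whose endpoints are already connected at
    that step level (a minimum-spanning network), and stopping at the
    connection limit (default: 95% parsimony probability for the alignment
    length).  Multi-step edges gain unlabelled inferred intermediate nodes.
    """
    labels = haplotypes.labels
    if not labels:
        raise ValueError("empty haplotype set")
    if limit is None:
        limit = parsimony_connection_limit(haplotypes.length)
    graph = nx.Graph()
    for lab in labels:
        graph.add_node(lab, inferred=False, frequency=int((frequencies or {}).get(lab, 0)))
    edges = sorted(
        (pairwise_differences(haplotypes, a, b), a, b)
        for i, a in enumerate(labels)
        for b in labels[i + 1:]
    )
    for steps, group in _group_by_steps(edges):
        if steps > limit:
            break
        # evaluate connectivity before this tier so co-minimal ties all enter
        reach = {lab: nx.node_connected_component(graph, lab) for lab in labels}
        for a, b in group:
            if b not in reach[a]:
                graph.add_edge(a, b, steps=steps)
    _insert_intermediates(graph)
    return SPNetwork(graph=graph, connection_limit=limit)


def _group_by_steps(edges):
    current: list[tuple[str, str]] = []
    step = None
    for s, a, b in edges:
        if s != step:
            if current:
                yield step, current
            step, current = s, []
        current.append((a, b))
    if current:
        yield step, current


def _insert_intermediates(graph: nx.Graph) -> None:
    for u, v, d in list(graph.edges(data=True)):
        steps = d["steps"]
        if steps <= 1:
            continue
        graph.remove_edge(u, v)
        prev = u
        for i in range(1, steps):
            node = f"{min(u, v)}~{max(u, v)}~{i}"
            graph.add_node(node, inferred=True, frequency=0)
            graph.add_edge(prev, node, steps=1)
            prev = node
        graph.add_edge(prev, v, steps=1)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_populations(matrix: DifferentiationMatrix) -> str:
    """Saitou-Nei neighbor-joining tree of populations, as newick text."""
    if len(matrix.populations) < 3:
        raise ValueError("need >= 3 populations for a neighbor-joining tree")
    dm = skbio.DistanceMatrix(matrix.values, ids=list(matrix.populations))
    tree = skbio.tree.nj(dm)
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
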