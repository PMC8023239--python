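"""Homologous Virus (HV) grouping from all-vs-all nucleotide similarity.

Contigs connected by strong pairwise similarity (e-value and
alignment-to-query-length filters) are treated as fragments/variants of the
same or highly related viruses. Group membership is the connected components
of the filtered hit graph (single-linkage semantics); components of size one,
and contigs with no passing hit at all, are singletons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .io import AbundanceMatrix

logger = logging.getLogger(__name__)

#: Sentinel taxon label for groups whose classified members disagree.
CONFLICT = "conflict"


@dataclass
class HVGrouping:
    """A partition of the contig catalog into HV groups and singletons."""

    groups: dict[str, frozenset[str]]
    singletons: frozenset[str]
    taxonomy: dict[str, str] = field(default_factory=dict)
    conflicts: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gid, members in self.groups.items():
            if len(members) < 2:
                raise ValueError(f"group {gid!r} has fewer than 2 members")
            if seen & members:
                raise ValueError(f"contig in two groups (group {gid!r})")
            seen |= members
        if seen & self.singletons:
            raise ValueError("contig both grouped and singleton")

    @property
    def catalog(self) -> frozenset[str]:
        out: set[str] = set(self.singletons)
        for members in self.groups.values():
            out |= members
        return frozenset(out)

    def group_of(self) -> dict[str, str]:
        """Map every contig to its group id (singletons map to themselves)."""
        out = {c: c for c in self.singletons}
        for gid, members in self.groups.items():
            for c in members:
                out[c] = gid
        return out

    def as_frame(self) -> pd.DataFrame:
        rows = sorted(self.group_of().items())
        return pd.DataFrame(
            {"contig_id": [c for c, _ in rows],
             "group_id": [g for _, g in rows],
             "is_singleton": [c in self.singletons for c, _ in rows]}
        )


def filter_hits(
    hits: pd.DataFrame,
    contig_lengths: pd.Series,
    max_evalue: float = 1e-20,
    min_hsp_query_ratio: float = 0.5,
    min_contig_length: float = 3000,
) -> list[tuple[str, str]]:
    """Reduce a directed hit table to undirected qualifying edges.

    A hit qualifies when ``evalue <= max_evalue``, its alignment spans at least
    ``min_hsp_query_ratio`` of the *query* contig, and both contigs are at
    least ``min_contig_length`` bp. Self-hits are discarded; an undirected
    edge exists if any directed hit between the pair qualifies.
    """
    if hits.empty:
        return []
    known = set(contig_lengths.index)
    participants = set(hits["qseqid"]) | set(hits["sseqid"])
    unknown = participants - known
    if unknown:
        raise KeyError(f"hits reference unknown contigs: {sorted(unknown)[:5]}")

    q = hits["qseqid"].to_numpy()
    s = hits["sseqid"].to_numpy()
    qlen = contig_lengths.loc[q].to_numpy(dtype=float)
    slen = contig_lengths.loc[s].to_numpy(dtype=float)
    keep = (
        (q != s)
        & (hits["evalue"].to_numpy(dtype=float) <= max_evalue)
        & (hits["length"].to_numpy(dtype=float) / qlen >= min_hsp_query_ratio)
        & (qlen >= min_contig_length)
        & (slen >= min_contig_length)
    )
    edges = {tuple(sorted(p)) for p in zip(q[keep], s[keep])}
    return sorted(edges)


def build_hv_groups(edges: Iterable[tuple[str, str]], catalog: Iterable[str]) -> HVGrouping:
    """Connected components of the edge graph over the full catalog.

    Components of size >= 2 become HV groups with deterministic ids ``HV0``,
    ``HV1``, ... assigned in order of descending size (ties broken by the
    lexicographically smallest member); everything else is a singleton.
    """
    catalog = list(dict.fromkeys(catalog))
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(catalog)
    for a, b in edges:
        if a not in graph or b not in graph:
            raise KeyError(f"edge ({a!r}, {b!r}) references contig outside catalog")
        graph.add_edge(a, b)

    components = [frozenset(c) for c in nx.connected_components(graph)]
    multi = sorted((c for c in components if len(c) >= 2),
                   key=lambda c: (-len(c), min(c)))
    singles = frozenset().union(*(c for c in components if len(c) == 1)) \
        if any(len(c) == 1 for c in components) else frozenset()
    groups = {f"HV{i}": members for i, members in enumerate(multi)}
    return HVGrouping(groups=groups, singletons=frozenset(singles))


def propagate_taxonomy(grouping: HVGrouping, contig_taxa: Mapping[str, str]) -> HVGrouping:
    """Extend marker-gene taxonomy from classified members to whole groups.

    A group whose classified members all agree receives that taxon; groups
    with no classified member stay unlabeled; disagreement is recorded under
    the ``conflict`` label with the discordant taxa listed, never raised.
    """
    taxonomy: dict[str, str] = {}
    conflicts: dict[str, list[str]] = {}
    for gid, members in grouping.groups.items():
        taxa = sorted({contig_taxa[c] for c in members if c in contig_taxa})
        if not taxa:
            continue
        if len(taxa) == 1:
            taxonomy[gid] = taxa[0]
        else:
            taxonomy[gid] = CONFLICT
            conflicts[gid] = taxa
            logger.warning("group %s has discordant taxa: %s", gid, taxa)
    for c in grouping.singletons:
        if c in contig_taxa:
            taxonomy[c] = contig_taxa[c]
    return HVGrouping(grouping.groups, grouping.singletons, taxonomy, conflicts)


def hv_diversity(abundance: AbundanceMatrix | pd.DataFrame, sample: str) -> tuple[int, float]:
    """Richness and Shannon index H = -sum p_i ln p_i of one sample.

    Expects an HV-level matrix to which the presence rule has already been
    applied (absent rows are zero). An empty sample yields (0, 0.0).
    """
    values = abundance.values if isinstance(abundance, AbundanceMatrix) else abundance
    col = values[sample].to_numpy(dtype=float)
    col = col[col > 0]
    richness = int(col.size)
    if richness == 0:
        logger.warning("sample %s has no present viruses; Shannon set to 0", sample)
        return 0, 0.0
    p = col / col.sum()
    shannon = float(-(p * np.log(p)).sum())
    return richness, shannon
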