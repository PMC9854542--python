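"""Assembly of lncRNA-miRNA-mRNA / circRNA-miRNA-mRNA networks and their
three-way integration.

A ceRNA triad (sponge, miRNA, mRNA) requires (1) the sponge-mRNA pair to be in
the screened positive co-expression list, (2) the same miRNA to have a passing
predicted site against both the sponge and the mRNA, and (3) all three members
to be significantly differential. The integrated network keeps only triads
whose miRNA sponges both a lncRNA and a circRNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd


@dataclass(frozen=True)
class CeRNATriad:
    sponge_id: str
    sponge_class: str  # 'lncRNA' or 'circRNA'
    mirna_id: str
    mrna_id: str
    coexpr_r: float
    directions: tuple[str, str, str]  # (sponge, miRNA, mRNA) up/down

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.sponge_class, self.mirna_id, self.sponge_id, self.mrna_id)


@dataclass
class CeRNANetwork:
    graph: nx.Graph
    triads: list[CeRNATriad] = field(default_factory=list)


def _de_direction(de: pd.DataFrame, feature: str) -> str | None:
    """Direction of a significantly differential feature, else None."""
    if feature not in de.index:
        return None
    row = de.loc[feature]
    if not bool(row["significant"]):
        return None
    return str(row["direction"])


def build_sponge_network(
    coexpr: pd.DataFrame,
    hits_mirna_mrna: pd.DataFrame,
    hits_mirna_sponge: pd.DataFrame,
    de_mrna: pd.DataFrame,
    de_sponge: pd.DataFrame,
    de_mirna: pd.DataFrame,
    sponge_class: str,
    antagonistic: bool = False,
) -> list[CeRNATriad]:
    """Enumerate triads for one sponge class.

    For each screened positive (mRNA, sponge) co-expression pair and each
    miRNA with passing hits against both members, emit one triad provided all
    three members are significantly differential. Identifiers present in hits
    but missing from the DE tables are skipped. Multiple sites of the same
    (miRNA, transcript) pair collapse to one triad. ``antagonistic`` further
    requires the miRNA's DE direction to oppose its targets'.
    """
    mirnas_of_mrna: dict[str, set[str]] = {}
    for _, row in hits_mirna_mrna.iterrows():
        mirnas_of_mrna.setdefault(str(row["transcript_id"]), set()).add(str(row["mirna_id"]))
    mirnas_of_sponge: dict[str, set[str]] = {}
    for _, row in hits_mirna_sponge.iterrows():
        mirnas_of_sponge.setdefault(str(row["transcript_id"]), set()).add(str(row["mirna_id"]))

    triads: dict[tuple, CeRNATriad] = {}
    for _, pair in coexpr.iterrows():
        mrna_id = str(pair["feature_a"])
        sponge_id = str(pair["feature_b"])
        r = float(pair["r"])
        if r <= 0:
            continue
        shared = mirnas_of_mrna.get(mrna_id, set()) & mirnas_of_sponge.get(sponge_id, set())
        if not shared:
            continue
        dir_mrna = _de_direction(de_mrna, mrna_id)
        dir_sponge = _de_direction(de_sponge, sponge_id)
        if dir_mrna is None or dir_sponge is None:
            continue
        for mirna_id in shared:
            dir_mirna = _de_direction(de_mirna, mirna_id)
            if dir_mirna is None:
                continue
            if antagonistic and (dir_mirna == dir_mrna or dir_mirna == dir_sponge):
                continue
            triad = CeRNATriad(
                sponge_id=sponge_id,
                sponge_class=sponge_class,
                mirna_id=mirna_id,
                mrna_id=mrna_id,
                coexpr_r=r,
                directions=(dir_sponge, dir_mirna, dir_mrna),
            )
            triads.setdefault(triad.key, triad)
    return sorted(triads.values(), key=lambda t: t.key)


def _network_from_triads(triads: list[CeRNATriad]) -> CeRNANetwork:
    g = nx.Graph()
    for t in triads:
        dir_sponge, dir_mirna, dir_mrna = t.directions
        g.add_node(t.sponge_id, node_class=t.sponge_class, direction=dir_sponge)
        g.add_node(t.mirna_id, node_class="miRNA", direction=dir_mirna)
        g.add_node(t.mrna_id, node_class="mRNA", direction=dir_mrna)
        g.add_edge(t.mirna_id, t.sponge_id, edge_type="regulation")
        g.add_edge(t.mirna_id, t.mrna_id, edge_type="regulation")
        g.add_edge(t.sponge_id, t.mrna_id, edge_type="co-expression")
    return CeRNANetwork(graph=g, triads=sorted(triads, key=lambda t: t.key))


def integrate_networks(
    lnc_triads: list[CeRNATriad], circ_triads: list[CeRNATriad]
) -> CeRNANetwork:
    """Keep only triads whose miRNA appears in at least one lncRNA triad AND
    at least one circRNA triad, then merge into one typed network."""
    shared = {t.mirna_id for t in lnc_triads} & {t.mirna_id for t in circ_triads}
    kept = [t for t in lnc_triads + circ_triads if t.mirna_id in shared]
    return _network_from_triads(kept)


def network_summary(net: CeRNANetwork) -> dict:
    """Triad count plus per-class up/down node counts and edge counts."""
    counts: dict[str, dict[str, int]] = {}
    for _, attrs in net.graph.nodes(data=True):
        cls = attrs.get("node_class", "unknown")
        direction = attrs.get("direction", "none")
        counts.setdefault(cls, {"up": 0, "down": 0})
        if direction in counts[cls]:
            counts[cls][direction] += 1
    edge_types = {"regulation": 0, "co-expression": 0}
    for _, _, attrs in net.graph.edges(data=True):
        kind = attrs.get("edge_type", "unknown")
        edge_types[kind] = edge_types.get(kind, 0) + 1
    return {
        "n_triads": len(net.triads),
        "n_nodes": net.graph.number_of_nodes(),
        "n_edges": net.graph.number_of_edges(),
        "nodes_by_class": counts,
        "edges_by_type": edge_types,
    }


def triads_table(triads: list[CeRNATriad]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sponge_id": t.sponge_id,
                "sponge_class": t.sponge_class,
                "mirna_id": t.mirna_id,
                "mrna_id": t.mrna_id,
                "coexpr_r": t.coexpr_r,
                "dir_sponge": t.directions[0],
                "dir_mirna": t.directions[1],
                "dir_mrna": t.directions[2],
            }
            for t in triads
        ],
        columns=[
            "sponge_id",
            "sponge_class",
            "mirna_id",
            "mrna_id",
            "coexpr_r",
            "dir_sponge",
            "dir_mirna",
            "dir_mrna",
        ],
    )


def network_to_sif(net: CeRNANetwork) -> list[tuple[str, str, str]]:
    """SIF triples (source, edge type, target) in deterministic order."""
    triples = []
    for a, b, attrs in net.graph.edges(data=True):
        src, dst = sorted([str(a), str(b)])
        triples.append((src, attrs.get("edge_type", "interacts"), dst))
    return sorted(triples)


def node_attributes_table(net: CeRNANetwork) -> pd.DataFrame:
    rows = [
        {"node": str(v), "node_class": a.get("node_class", ""), "direction": a.get("direction", "")}
        for v, a in net.graph.nodes(data=True)
    ]
    return pd.DataFrame(rows, columns=["node", "node_class", "direction"]).sort_values(
        "node", kind="mergesort"
    ).reset_index(drop=True)
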