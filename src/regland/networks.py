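"""Directed TF-TF regulatory network from bound footprint calls.

An edge A->B means a bound binding site of TF A lies within the gene
encoding TF B or within its promoter window (-2 kb .. +200 bp around the
TSS, strand-oriented). Edges are classed ``tss`` when every supporting site
is in the promoter window, ``non_tss`` when every site is elsewhere within
the gene, and ``both`` otherwise. The promoter window used here is
deliberately distinct from the 200 bp TSS window used for NFR
classification; both are named constants so the two definitions cannot
collide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from regland.footprints import FootprintCall
from regland.genome_io import GenomeAnnotation

# promoter window for network edges, strand-oriented around the TSS
NETWORK_TSS_WINDOW = (-2000, 200)
# TSS window for NFR classification (chromatin_states.classify_nfr_tss)
NFR_TSS_WINDOW = 200

EDGE_CLASSES = ("tss", "non_tss", "both")


@dataclass(frozen=True)
class NetworkEdge:
    """Directed TF->TF link supported by >= 1 bound site in the target gene."""

    source_tf: str
    target_tf: str
    target_gene: str
    edge_class: str
    n_supporting_sites: int
    phenotypes: frozenset[str]
    self_loop: bool = False

    def __post_init__(self) -> None:
        if self.edge_class not in EDGE_CLASSES:
            raise ValueError(f"edge_class must be one of {EDGE_CLASSES}")
        if self.n_supporting_sites < 1:
            raise ValueError("an edge needs >= 1 supporting site")


def build_tf_network(
    bound_calls: Sequence[FootprintCall],
    annotation: GenomeAnnotation,
    tf_gene_map: Mapping[str, str],
    tss_window: tuple[int, int] = NETWORK_TSS_WINDOW,
) -> list[NetworkEdge]:
    """Construct the directed TF-TF network from bound sites.

    Only calls flagged bound contribute. Sites of motifs missing from
    ``tf_gene_map`` are still usable as sources; an empty map is an error.
    """
    if not tf_gene_map:
        raise ValueError("tf_gene_map is empty; no genes can be targeted")
    gene_to_tf = {g: m for m, g in tf_gene_map.items()}
    lo, hi = tss_window

    windows = []  # (chrom, w_start, w_end, g_start, g_end, gene_id, tf)
    for gid, tf in sorted(gene_to_tf.items()):
        if gid not in annotation.genes:
            warnings.warn(f"tf_gene_map gene {gid} absent from annotation; skipped")
            continue
        g = annotation.genes[gid]
        tss = annotation.tss(gid)
        if g.strand == "-":
            w_start, w_end = tss - hi, tss - lo + 1
        else:
            w_start, w_end = tss + lo, tss + hi + 1
        windows.append((g.chrom, w_start, w_end, g.start, g.end, gid, tf))

    support: dict[tuple[str, str, str], dict] = {}
    for call in bound_calls:
        if not call.bound:
            continue
        iv = call.site.interval
        mid = iv.midpoint
        for chrom, ws, we, gs, ge, gid, tf in windows:
            if chrom != iv.chrom:
                continue
            in_window = ws <= mid < we
            in_gene = gs <= mid < ge
            if not (in_window or in_gene):
                continue
            d = support.setdefault(
                (call.site.motif_id, tf, gid), {"cls": set(), "ph": set(), "n": 0}
            )
            d["cls"].add("tss" if in_window else "non_tss")
            d["n"] += 1
            if call.phenotype:
                d["ph"].add(call.phenotype)

    edges = []
    for (src, tgt, gid), d in sorted(support.items()):
        cls = "both" if len(d["cls"]) == 2 else next(iter(d["cls"]))
        edges.append(
            NetworkEdge(
                source_tf=src,
                target_tf=tgt,
                target_gene=gid,
                edge_class=cls,
                n_supporting_sites=d["n"],
                phenotypes=frozenset(d["ph"]),
                self_loop=src == tgt,
            )
        )
    return edges


def merge_phenotype_networks(per_phenotype: Mapping[str, Sequence[NetworkEdge]]) -> list[NetworkEdge]:
    """Union of per-phenotype networks with a phenotype-set annotation."""
    merged: dict[tuple[str, str, str], dict] = {}
    for ph, edges in sorted(per_phenotype.items()):
        for e in edges:
            d = merged.setdefault(
                (e.source_tf, e.target_tf, e.target_gene),
                {"cls": set(), "ph": set(), "n": 0},
            )
            d["cls"].add(e.edge_class)
            d["ph"].add(ph)
            d["ph"].update(e.phenotypes)
            d["n"] += e.n_supporting_sites
    out = []
    for (src, tgt, gid), d in sorted(merged.items()):
        cls_set = d["cls"] - {"both"}
        cls = "both" if "both" in d["cls"] or len(cls_set) == 2 else next(iter(cls_set))
        out.append(
            NetworkEdge(src, tgt, gid, cls, d["n"], frozenset(d["ph"]), src == tgt)
        )
    return out


def subnetwork_from_root(
    edges: Sequence[NetworkEdge], root_tf: str, max_depth: int | None = None
) -> list[NetworkEdge]:
    """Breadth-first closure following edge direction from ``root_tf``.

    Deterministic ordering (by depth, then lexical); each edge reported once
    even through cycles.
    """
    nodes = {e.source_tf for e in edges} | {e.target_tf for e in edges}
    if root_tf not in nodes:
        raise ValueError(
            f"root {root_tf!r} not in network; available TFs: {sorted(nodes)}"
        )
    out_edges: dict[str, list[NetworkEdge]] = {}
    for e in sorted(edges, key=lambda e: (e.source_tf, e.target_tf)):
        out_edges.setdefault(e.source_tf, []).append(e)

    result: list[NetworkEdge] = []
    seen_edges: set[tuple[str, str, str]] = set()
    visited = {root_tf}
    frontier = [root_tf]
    depth = 0
    while frontier and (max_depth is None or depth < max_depth):
        nxt: list[str] = []
        for node in frontier:
            for e in out_edges.get(node, []):
                key = (e.source_tf, e.target_tf, e.target_gene)
                if key in seen_edges:
                    continue
                seen_edges.add(key)
                result.append(e)
                if e.target_tf not in visited:
                    visited.add(e.target_tf)
                    nxt.append(e.target_tf)
        frontier = sorted(set(nxt))
        depth += 1
    return result


def to_networkx(edges: Sequence[NetworkEdge]) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    for e in edges:
        g.add_edge(
            e.source_tf,
            e.target_tf,
            gene=e.target_gene,
            edge_class=e.edge_class,
            n_sites=e.n_supporting_sites,
            phenotypes=",".join(sorted(e.phenotypes)),
        )
    return g


_DOT_COLORS = {"tss": "aquamarine3", "non_tss": "purple", "both": "gray"}

EXPORT_DIALECTS = ("tsv", "dot")


def export_network(
    edges: Sequence[NetworkEdge], path: str | Path, dialect: str = "tsv"
) -> None:
    """Write the edge list as TSV or Graphviz DOT (edge color by class).

    Output is stably sorted for reproducible diffs.
    """
    if dialect not in EXPORT_DIALECTS:
        raise ValueError(f"dialect must be one of {EXPORT_DIALECTS}")
    ordered = sorted(edges, key=lambda e: (e.source_tf, e.target_tf, e.target_gene))
    with open(path, "w") as fh:
        if dialect == "tsv":
            fh.write("source\ttarget\tgene\tclass\tn_sites\tphenotypes\n")
            for e in ordered:
                fh.write(
                    f"{e.source_tf}\t{e.target_tf}\t{e.target_gene}\t{e.edge_class}\t"
                    f"{e.n_supporting_sites}\t{','.join(sorted(e.phenotypes))}\n"
                )
        else:
            fh.write("digraph tf_network {\n")
            for e in ordered:
                fh.write(
                    f'  "{e.source_tf}" -> "{e.target_tf}" '
                    f'[color={_DOT_COLORS[e.edge_class]}, label="{e.target_gene}"];\n'
                )
            fh.write("}\n")


def read_network_tsv(path: str | Path) -> list[NetworkEdge]:
    edges = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("source\t"):
            raise ValueError(f"{path}: missing network TSV header")
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            edges.append(
                NetworkEdge(
                    cols[0], cols[1], cols[2], cols[3], int(cols[4]),
                    frozenset(cols[5].split(",")) if len(cols) > 5 and cols[5] else frozenset(),
                    cols[0] == cols[1],
                )
            )
    return edges
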