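"""Complex-membership interactome and the biomarker subgraph.

Protein complexes (CORUM / hu.MAP-style membership lists) are expanded to
cliques — co-membership is taken as pairwise interaction evidence without
naming a hub — and merged into one simple undirected graph keyed by gene
symbol. The biomarker subgraph is the induced subgraph on the union of the
supplied biomarker gene sets, annotated with a class per node and the mean
normalized expression of the castration-resistant lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import pandas as pd

from .differential import BiomarkerSets
from .preprocess import NormalizedTable
from .tables import ConfigurationError, parse_site_key

log = logging.getLogger(__name__)

NODE_CLASSES = (
    "protein_up", "protein_down", "phospho_up", "phospho_down",
    "CR_only", "CS_only", "mixed",
)


def read_complex_file(path) -> dict[str, list[str]]:
    """Membership TSV: complex_id <tab> semicolon-separated gene symbols."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cid, _, members = line.partition("\t")
            out[cid] = [g for g in members.split(";") if g]
    return out


def build_complex_network(complex_files: list) -> nx.Graph:
    """Union of clique expansions of every complex in every resource.

    Edges carry ``sources``, the sorted list of complex ids providing the
    co-membership evidence. Complexes with <2 members are skipped (logged).
    """
    g = nx.Graph()
    for path in complex_files:
        for cid, members in read_complex_file(path).items():
            members = sorted(set(members))
            if len(members) < 2:
                log.info("skipping complex %s with <2 members", cid)
                continue
            g.add_nodes_from(members)
            for a, b in combinations(members, 2):
                if g.has_edge(a, b):
                    sources = set(g[a][b]["sources"].split(";"))
                    sources.add(cid)
                    g[a][b]["sources"] = ";".join(sorted(sources))
                else:
                    g.add_edge(a, b, sources=cid)
    log.info("complex network: %d nodes, %d edges", g.number_of_nodes(), g.number_of_edges())
    return g


def _site_parent_genes(site_ids: list[str], site_gene_map: pd.Series | None) -> set[str]:
    """Map phosphosite ids to parent gene symbols.

    Uses the table's gene-symbol annotation when supplied, else the accession
    part of the site key.
    """
    genes: set[str] = set()
    for sid in site_ids:
        if site_gene_map is not None and sid in site_gene_map.index:
            sym = str(site_gene_map.loc[sid]).split(";")[0]
            if sym:
                genes.add(sym)
                continue
        genes.add(parse_site_key(sid)[0])
    return genes


@dataclass
class BiomarkerGraph:
    graph: nx.Graph
    isolated: list[str]          # biomarker genes present in the net but edge-free in the set
    missing: list[str]           # biomarker genes absent from the interactome
    component_sizes: list[int]


def biomarker_subgraph(
    net: nx.Graph,
    protein_sets: BiomarkerSets,
    phospho_sets: BiomarkerSets | None = None,
    expression: NormalizedTable | None = None,
    protein_gene_map: pd.Series | None = None,
    site_gene_map: pd.Series | None = None,
) -> BiomarkerGraph:
    """Induced subgraph on the union of biomarker genes, class-annotated.

    Classes combine both layers' resistance and presence/absence sets:
    ``protein_up/down`` from the proteome CR-vs-CS markers, ``phospho_up/down``
    from the phosphoproteome markers mapped to parent genes, ``CR_only`` /
    ``CS_only`` from either layer's rescue sets. Proteins map to their first
    listed gene symbol (via ``protein_gene_map`` when feature ids are not
    symbols); phosphosites to their parent protein's symbol. Nodes in several
    classes get class ``mixed`` (full list kept in ``classes``). Isolated
    biomarker genes are excluded from the graph and listed separately.
    ``expression`` supplies the node attribute ``cr_expression``: the mean
    normalized expression over the castration-resistant lines.
    """

    def to_genes(feature_ids: list[str], is_site: bool) -> set[str]:
        if is_site:
            return _site_parent_genes(feature_ids, site_gene_map)
        if protein_gene_map is None:
            return {f.split(";")[0] for f in feature_ids}
        return {
            str(protein_gene_map.get(f, f)).split(";")[0] for f in feature_ids
        }

    phos = phospho_sets or BiomarkerSets()
    class_members = {
        "protein_up": to_genes(protein_sets.cr_up, False),
        "protein_down": to_genes(protein_sets.cr_down, False),
        "phospho_up": to_genes(phos.cr_up, True),
        "phospho_down": to_genes(phos.cr_down, True),
        "CR_only": to_genes(protein_sets.cr_only, False) | to_genes(phos.cr_only, True),
        "CS_only": to_genes(protein_sets.cs_only, False) | to_genes(phos.cs_only, True),
    }
    union = set().union(*class_members.values())
    present = sorted(union & set(net.nodes))
    missing = sorted(union - set(net.nodes))
    sub = net.subgraph(present).copy()
    isolated = sorted(n for n, d in sub.degree() if d == 0)
    sub.remove_nodes_from(isolated)

    for node in sub.nodes:
        classes = sorted(c for c, members in class_members.items() if node in members)
        sub.nodes[node]["classes"] = ";".join(classes)
        sub.nodes[node]["klass"] = classes[0] if len(classes) == 1 else "mixed"

    if expression is not None:
        design = expression.design
        cr_samples = [s for ln in design.cr_lines for s in design.samples_for_line(ln)]
        primary = (
            expression.gene_symbols.fillna("").str.split(";").str[0]
            if expression.gene_symbols is not None
            else pd.Series(expression.values.index, index=expression.values.index)
        )
        mean_cr = expression.values[cr_samples].mean(axis=1)
        by_gene = mean_cr.groupby(primary.reindex(mean_cr.index)).mean()
        for node in sub.nodes:
            if node in by_gene.index and pd.notna(by_gene[node]):
                sub.nodes[node]["cr_expression"] = float(by_gene[node])

    sizes = sorted((len(c) for c in nx.connected_components(sub)), reverse=True)
    return BiomarkerGraph(
        graph=sub, isolated=isolated, missing=missing, component_sizes=sizes
    )


def export_graph(bg: BiomarkerGraph | nx.Graph, fmt: str, path) -> None:
    """Write the graph as SIF (``a pp b`` lines) or GraphML; deterministic."""
    g = bg.graph if isinstance(bg, BiomarkerGraph) else bg
    if fmt == "sif":
        with open(path, "w") as fh:
            fh.write("#node1\tinteraction\tnode2\n")
            for a, b in sorted((tuple(sorted(e)) for e in g.edges)):
                fh.write(f"{a}\tpp\t{b}\n")
    elif fmt == "graphml":
        ordered = nx.Graph()
        ordered.add_nodes_from(sorted(g.nodes(data=True)))
        ordered.add_edges_from(
            sorted((*sorted((a, b)), d) for a, b, d in g.edges(data=True))
        )
        nx.write_graphml(ordered, path)
    else:
        raise ConfigurationError(f"unknown export format {fmt!r}; use 'sif' or 'graphml'")


def import_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
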