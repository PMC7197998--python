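"""Entropy-based main-effect and interaction measures.

All quantities are plug-in (maximum-likelihood) Shannon estimates in bits.
The pairwise interaction information

    IG(A;B;C) = I(A,B;C) - I(A;C) - I(B;C)

treats the SNP pair as a joint 9-level attribute; positive values mean the
pair carries information about the phenotype beyond its parts (synergy,
i.e. epistasis), negative values redundancy.  The interaction graph scales
node and edge values to percent of the phenotype entropy H(C), which is how
MDR-style interaction maps are conventionally drawn.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .io_model import MISSING, Dataset, ValidationError


def entropy(values) -> float:
    """Plug-in Shannon entropy of a discrete sample, in bits (0*log0 = 0)."""
    values = np.asarray(values)
    if values.size == 0:
        raise ValidationError("entropy of an empty sample is undefined")
    _, counts = np.unique(values, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _joint(x, y) -> np.ndarray:
    """Integer codes of the joint (x, y) sample."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValidationError("samples have different lengths")
    _, xi = np.unique(x, return_inverse=True)
    levels, yi = np.unique(y, return_inverse=True)
    return xi * len(levels) + yi


def mutual_information(x, c) -> float:
    """I(X;C) = H(X) + H(C) - H(X,C) on the same sample, in bits."""
    return entropy(x) + entropy(c) - entropy(_joint(x, c))


def pairwise_gain(a, b, c) -> float:
    """Interaction information IG(A;B;C), signed bits.

    Computed with the joint (A,B) attribute on the identical sample, so the
    chain identity I(A,B;C) = I(A;C) + I(B;C) + IG(A;B;C) holds exactly.
    """
    ab = _joint(a, b)
    return mutual_information(ab, c) - mutual_information(a, c) - mutual_information(b, c)


def interaction_graph(dataset: Dataset, snp_ids: list[str] | None = None) -> nx.Graph:
    """Complete interaction graph over the requested SNPs.

    Node attribute ``gain_bits``/``gain_pct``: main-effect information
    I(SNP; phenotype), absolute and as percent of the phenotype entropy.
    Edge attributes: pairwise interaction information, signed.  Missing
    genotypes are dropped listwise per node / per pair, and H(C) in the
    percentage denominators is recomputed on the same subsample.
    """
    ids = snp_ids if snp_ids is not None else dataset.snp_ids
    if len(ids) < 2:
        raise ValidationError("interaction graph needs at least two SNPs")
    pheno = dataset.phenotype
    base = entropy(pheno)
    if base == 0.0:
        raise ValidationError("phenotype entropy is zero (single class)")
    G = nx.Graph(base_entropy=base)
    cols = {s: dataset.column(s) for s in ids}
    for s in ids:
        ok = cols[s] != MISSING
        if not ok.any():
            gain = 0.0
            pct = 0.0
        else:
            hc = entropy(pheno[ok])
            gain = mutual_information(cols[s][ok], pheno[ok])
            pct = 100.0 * gain / hc if hc > 0 else 0.0
        G.add_node(s, gain_bits=gain, gain_pct=pct)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ok = (cols[a] != MISSING) & (cols[b] != MISSING)
            if not ok.any():
                gain = pct = 0.0
            else:
                hc = entropy(pheno[ok])
                gain = pairwise_gain(cols[a][ok], cols[b][ok], pheno[ok])
                pct = 100.0 * gain / hc if hc > 0 else 0.0
            G.add_edge(a, b, gain_bits=gain, gain_pct=pct)
    return G


def graph_to_dict(G: nx.Graph) -> dict:
    """JSON-ready representation of an interaction graph."""
    return {
        "base_entropy_bits": G.graph["base_entropy"],
        "nodes": {n: dict(G.nodes[n]) for n in G.nodes},
        "edges": [
            {"a": a, "b": b, **G.edges[a, b]} for a, b in sorted(G.edges)
        ],
    }


def graph_to_dot(G: nx.Graph) -> str:
    """Graphviz DOT export; edge color encodes synergy (red) vs redundancy
    (green), matching the usual interaction-map rendering."""
    lines = ["graph interactions {"]
    for n in sorted(G.nodes):
        lines.append(f'  "{n}" [label="{n}\\n{G.nodes[n]["gain_pct"]:.2f}%"];')
    for a, b in sorted(G.edges):
        pct = G.edges[a, b]["gain_pct"]
        color = "red" if pct > 0 else "green"
        lines.append(f'  "{a}" -- "{b}" [label="{pct:.2f}%", color={color}];')
    lines.append("}")
    return "\n".join(lines) + "\n"
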