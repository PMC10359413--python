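"""FA elongation/desaturation reaction-network pathway analysis.

A directed reaction network over fatty acids (nodes keyed by the
double-bond-position-aware ``C:Dn-x`` nomenclature) encodes which chains
can be converted into which by chain elongation (+2 carbons), chain
shortening (-2 carbons) and desaturation (+1 double bond).  The default
table, shipped as an editable TSV, is a best-effort reconstruction of
the standard mammalian pathways (SFA elongation ladder, the delta-9 MUFA
branches, and the n-6/n-3 PUFA routes including the C24 shortening
steps); it can be replaced wholesale by the user.

Against a measured profile the network yields, per node, a *level change
score* (mean_RA - mean_OA) / mean_OA, and, per reaction edge, the
within-diagnosis Pearson correlation between substrate and product
mol-% computed separately in each diagnosis group.  An edge significant
within a diagnosis (p <= alpha) marks the reaction as a candidate
dominant biosynthesis route for the product in that diagnosis; the
four-way class (significant in neither / one / both diagnoses) is the
cross-diagnosis comparison.  Reactions whose intermediate FAs were not
measured are bridged by *effective* edges connecting the nearest
measured endpoints.
"""

from __future__ import annotations

import importlib.resources
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .names import FAName, parse_fa_name

__all__ = [
    "load_reactions",
    "build_network",
    "level_change",
    "annotate_edges",
    "classify_edge",
    "export_network",
]


class PathwayError(ValueError):
    pass


_DELTAS = {  # kind -> (carbon delta, double-bond delta)
    "elongation": (2, 0),
    "chain_shortening": (-2, 0),
    "desaturation": (0, 1),
}


def _validate_reaction(sub: FAName, prod: FAName, kind: str) -> None:
    if kind not in _DELTAS:
        raise PathwayError(f"unknown reaction kind {kind!r}")
    dc, db = _DELTAS[kind]
    if prod.carbons - sub.carbons != dc or prod.double_bonds - sub.double_bonds != db:
        raise PathwayError(
            f"{kind} {sub.label} -> {prod.label} violates the "
            f"({dc:+d} C, {db:+d} DB) stoichiometry"
        )
    if sub.label == prod.label:
        raise PathwayError(f"self-loop on {sub.label}")
    series_created = sub.series == "none" and kind == "desaturation"
    if not series_created and sub.series != prod.series:
        raise PathwayError(
            f"{kind} {sub.label} -> {prod.label} changes the n-series"
        )


def load_reactions(path=None) -> pd.DataFrame:
    """Read a (substrate, product, kind) reaction table and validate its
    stoichiometry; the packaged default is used when ``path`` is None."""
    if path is None:
        ref = importlib.resources.files("lipidsig.data") / "reactions.tsv"
        with importlib.resources.as_file(ref) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    required = {"substrate", "product", "kind"}
    if not required <= set(table.columns):
        raise PathwayError(f"reaction table needs columns {sorted(required)}")
    for _, row in table.iterrows():
        _validate_reaction(
            parse_fa_name(row["substrate"]), parse_fa_name(row["product"]),
            row["kind"],
        )
    return table


def build_network(
    measured: set[str] | list[str],
    reactions: pd.DataFrame | None = None,
) -> nx.DiGraph:
    """Assemble the reaction network over a set of measured FA labels.

    Nodes carry ``measured``, ``carbons`` and ``double_bonds``
    attributes.  Direct edges (``effective=False``) connect two measured
    FAs related by one reaction; *effective* edges (``effective=True``)
    connect measured FAs linked by a directed chain whose interior nodes
    are all unmeasured, with the traversed path and summed deltas
    recorded.  Measured FAs absent from the reaction table become
    isolated nodes with a warning.
    """
    if reactions is None:
        reactions = load_reactions()
    measured = {parse_fa_name(m).label for m in measured}
    g = nx.DiGraph()
    for _, row in reactions.iterrows():
        for lab in (row["substrate"], row["product"]):
            if lab not in g:
                nm = parse_fa_name(lab)
                g.add_node(lab, measured=lab in measured,
                           carbons=nm.carbons, double_bonds=nm.double_bonds)
        g.add_edge(row["substrate"], row["product"], kind=row["kind"],
                   effective=False)
    orphans = sorted(measured - set(g.nodes))
    if orphans:
        warnings.warn(
            f"measured FAs absent from the reaction table: {orphans}",
            stacklevel=2,
        )
        for lab in orphans:
            nm = parse_fa_name(lab)
            g.add_node(lab, measured=True, carbons=nm.carbons,
                       double_bonds=nm.double_bonds)
    # contract maximal unmeasured chains into effective edges
    base_edges = list(g.edges(data=True))
    base = nx.DiGraph()
    base.add_edges_from(base_edges)
    for u in [n for n in g.nodes if g.nodes[n]["measured"]]:
        # depth-first through unmeasured nodes only
        stack = [(v, [u, v]) for v in base.successors(u)] if u in base else []
        while stack:
            node, path = stack.pop()
            if g.nodes[node]["measured"]:
                if len(path) > 2 and not g.has_edge(u, node):
                    kinds = [
                        base.edges[a, b]["kind"] for a, b in zip(path, path[1:])
                    ]
                    g.add_edge(u, node, kind="+".join(kinds), effective=True,
                               path="|".join(path))
                continue
            for nxt in base.successors(node):
                if nxt not in path:
                    stack.append((nxt, path + [nxt]))
    return g


def level_change(profiles, ref: str = "OA", alt: str = "RA") -> pd.Series:
    """Relative mean level change of every variable, (mean_alt - mean_ref)
    / mean_ref; FAs with zero reference mean are reported as NaN with a
    warning."""
    diag = profiles.meta["diagnosis"]
    for level in (ref, alt):
        if level not in set(diag):
            raise PathwayError(f"diagnosis level {level!r} not present")
    m_ref = profiles.values[diag == ref].mean(axis=0)
    m_alt = profiles.values[diag == alt].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lc = (m_alt - m_ref) / m_ref
    zero = m_ref.index[m_ref == 0].tolist()
    if zero:
        warnings.warn(
            f"zero reference mean; level change undefined for: {zero}",
            stacklevel=2,
        )
        lc[zero] = np.nan
    return lc.rename("level_change")


def classify_edge(p_ref: float, p_alt: float, alpha: float = 0.05,
                  ref: str = "OA", alt: str = "RA") -> str:
    """Four-way significance class of an edge from its within-diagnosis
    p-values; a pure function of (p_ref <= alpha, p_alt <= alpha)."""
    s_ref, s_alt = p_ref <= alpha, p_alt <= alpha
    if s_ref and s_alt:
        return "sig_both"
    if s_ref:
        return f"sig_{ref}_only"
    if s_alt:
        return f"sig_{alt}_only"
    return "sig_neither"


def annotate_edges(
    network: nx.DiGraph,
    profiles,
    alpha: float = 0.05,
    ref: str = "OA",
    alt: str = "RA",
) -> pd.DataFrame:
    """Within-diagnosis Pearson correlation of every network edge.

    For each edge whose endpoints are both in the profile, the substrate
    and product mol-% columns are correlated within the ``ref`` samples
    and, separately, within the ``alt`` samples; the edge class follows
    :func:`classify_edge`.  Edges with an endpoint missing from the
    profile are skipped with a warning.
    """
    diag = profiles.meta["diagnosis"]
    for level in (ref, alt):
        if (diag == level).sum() < 3:
            raise PathwayError(
                f"diagnosis {level!r} needs >= 3 samples for correlation"
            )
    cols = set(profiles.values.columns)
    rows = []
    skipped = []
    for u, v, data in network.edges(data=True):
        if u not in cols or v not in cols:
            # only flag edges the network believes are measurable; edges
            # touching hollow (unmeasured) nodes are expected to be absent
            if network.nodes[u]["measured"] and network.nodes[v]["measured"]:
                skipped.append((u, v))
            continue
        rec = {"substrate": u, "product": v, "kind": data["kind"],
               "effective": data["effective"]}
        for tag, level in (("ref", ref), ("alt", alt)):
            sub = profiles.values.loc[diag == level, u].to_numpy(float)
            prod = profiles.values.loc[diag == level, v].to_numpy(float)
            r, p = stats.pearsonr(sub, prod)
            rec[f"r_{level}"] = r
            rec[f"p_{level}"] = p
        rec["class"] = classify_edge(rec[f"p_{ref}"], rec[f"p_{alt}"],
                                     alpha, ref, alt)
        rows.append(rec)
    if skipped:
        warnings.warn(
            f"edges skipped (endpoint not in profile): {skipped}", stacklevel=2
        )
    out = pd.DataFrame(
        rows, columns=["substrate", "product", "kind", "effective",
                       f"r_{ref}", f"p_{ref}", f"r_{alt}", f"p_{alt}", "class"]
    )
    return out


def export_network(
    network: nx.DiGraph,
    annotations: pd.DataFrame | None = None,
    level_changes: pd.Series | None = None,
    prefix: str = "network",
) -> dict[str, str]:
    """Write GraphML, DOT and a TSV edge table.

    Node attributes: carbons, measured, level_change; edge attributes:
    kind, effective, and (when annotated) per-diagnosis r/p and class.
    Returns the written file paths.
    """
    g = network.copy()
    if level_changes is not None:
        for node in g.nodes:
            if node in level_changes.index and np.isfinite(level_changes[node]):
                g.nodes[node]["level_change"] = float(level_changes[node])
    if annotations is not None:
        keyed = annotations.set_index(["substrate", "product"])
        for u, v in g.edges:
            if (u, v) in keyed.index:
                row = keyed.loc[(u, v)]
                for col in keyed.columns:
                    if col in ("kind", "effective"):
                        continue
                    val = row[col]
                    g.edges[u, v][col] = (
                        float(val) if isinstance(val, (int, float, np.floating))
                        else str(val)
                    )
    paths = {
        "graphml": f"{prefix}.graphml",
        "dot": f"{prefix}.dot",
        "edges": f"{prefix}_edges.tsv",
    }
    nx.write_graphml(g, paths["graphml"])
    _write_dot(g, paths["dot"])
    if annotations is not None:
        annotations.to_csv(paths["edges"], sep="\t", index=False)
    else:
        nx.to_pandas_edgelist(g, source="substrate", target="product").to_csv(
            paths["edges"], sep="\t", index=False
        )
    return paths


def _write_dot(g: nx.DiGraph, path: str) -> None:
    """Minimal Graphviz DOT writer (no pydot dependency)."""

    def q(s):
        return '"' + str(s).replace('"', r"\"") + '"'

    with open(path, "w") as fh:
        fh.write("digraph FA_network {\n")
        for node, data in g.nodes(data=True):
            attrs = ", ".join(f"{k}={q(v)}" for k, v in sorted(data.items()))
            fh.write(f"  {q(node)} [{attrs}];\n")
        for u, v, data in g.edges(data=True):
            attrs = ", ".join(f"{k}={q(v_)}" for k, v_ in sorted(data.items()))
            fh.write(f"  {q(u)} -> {q(v)} [{attrs}];\n")
        fh.write("}\n")
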