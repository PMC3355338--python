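"""Graph exporters: GraphML, DOT and a schema-stable JSON.

All exporters are deterministic for a given graph (element order follows
node/edge insertion order, which the builders keep stable).
"""

from __future__ import annotations

import json

import networkx as nx

from .model import BnglError, Diagnostic

JSON_SCHEMA_VERSION = 1
FORMATS = ("graphml", "dot", "json")


def export_graph(graph, fmt: str) -> str:
    """Render a networkx graph in one of the supported text formats."""
    if fmt == "graphml":
        return "\n".join(nx.generate_graphml(graph, named_key_ids=True))
    if fmt == "dot":
        return _to_dot(graph)
    if fmt == "json":
        return _to_json(graph)
    raise BnglError(Diagnostic("error", f"unknown export format {fmt!r}"))


def import_graph(text: str, fmt: str):
    if fmt == "graphml":
        return nx.parse_graphml(text)
    if fmt == "json":
        payload = json.loads(text)
        g = nx.MultiDiGraph() if payload.get("directed") else nx.Graph()
        for node in payload["nodes"]:
            attrs = {k: v for k, v in node.items() if k != "id"}
            g.add_node(node["id"], **attrs)
        for edge in payload["edges"]:
            attrs = {k: v for k, v in edge.items()
                     if k not in ("source", "target")}
            g.add_edge(edge["source"], edge["target"], **attrs)
        return g
    raise BnglError(Diagnostic("error", f"cannot import format {fmt!r}"))


def _quote(s) -> str:
    return '"' + str(s).replace('"', '\\"') + '"'


def _to_dot(graph) -> str:
    directed = graph.is_directed()
    lines = ["digraph G {" if directed else "graph G {"]
    arrow = "->" if directed else "--"
    for node, attrs in graph.nodes(data=True):
        body = ",".join(f"{k}={_quote(v)}" for k, v in sorted(attrs.items()))
        lines.append(f"  {_quote(node)}" + (f" [{body}]" if body else "")
                     + ";")
    for edge in graph.edges(data=True):
        u, v, attrs = edge
        body = ",".join(f"{k}={_quote(w)}" for k, w in sorted(attrs.items()))
        lines.append(f"  {_quote(u)} {arrow} {_quote(v)}"
                     + (f" [{body}]" if body else "") + ";")
    lines.append("}")
    return "\n".join(lines) + "\n"


def _to_json(graph) -> str:
    payload = {
        "schema_version": JSON_SCHEMA_VERSION,
        "directed": graph.is_directed(),
        "nodes": [{"id": n, **{k: v for k, v in attrs.items()}}
                  for n, attrs in graph.nodes(data=True)],
        "edges": [{"source": u, "target": v, **attrs}
                  for u, v, attrs in graph.edges(data=True)],
    }
    return json.dumps(payload, indent=2, sort_keys=False) + "\n"
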