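"""Assemble and serialize the color-coded interaction network.

The network's topology is exactly the user's OTU association network: nodes
are OTUs shaded by the percent identity of their genome match (darker =
closer match, a visual cue against over-interpreting poorly matched nodes),
and edges carry the association weight plus the predicted interaction, colored
green (positive), red (negative) or grey (no interaction).

Serialization is to static, reproducible artifacts: a force-layout-style JSON
(``nodes``/``links``), GraphML, and a self-contained HTML page embedding the
JSON and an SVG rendering of a seeded Fruchterman–Reingold layout.
"""

from __future__ import annotations

import html as _html
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .interactions import InteractionRecord
from .otu_prep import AssociationTable, GenomeMatch

__all__ = [
    "InteractionNetwork",
    "build_network",
    "write_network",
    "node_shade",
    "POLARITY_COLOR",
]

logger = logging.getLogger(__name__)

POLARITY_COLOR = {"positive": "green", "negative": "red", "none": "grey"}

#: 5-step light→dark grey ramp for identities 80–100 %.
_SHADE_RAMP = ("#d9d9d9", "#ababab", "#7e7e7e", "#525252", "#262626")
_LOW_IDENTITY = 80.0

_LAYOUT_SEED = 42
_LAYOUT_ITERATIONS = 100


@dataclass
class NetworkNode:
    otu_id: str
    identity: float  # percent identity of the genome match, 0–100


@dataclass
class NetworkEdge:
    otu_a: str
    otu_b: str
    weight: float  # association weight from the input table
    color: str  # green / red / grey
    type_label: str


@dataclass
class InteractionNetwork:
    nodes: list[NetworkNode]
    edges: list[NetworkEdge]


def node_shade(identity: float) -> tuple[str, bool]:
    """Fill color and low-confidence flag for a node.

    Identity maps linearly from 80–100 % onto the 5-step grey ramp; below
    80 % the node gets the lightest shade and a dashed border as a
    low-confidence cue.
    """
    if identity < _LOW_IDENTITY:
        return _SHADE_RAMP[0], True
    step = min(len(_SHADE_RAMP) - 1, int((identity - _LOW_IDENTITY) // 4))
    return _SHADE_RAMP[step], False


def build_network(
    assoc: AssociationTable,
    matches: Sequence[GenomeMatch],
    records: Sequence[InteractionRecord],
) -> InteractionNetwork:
    """Join the association topology with matches and interaction calls.

    Edge color is a pure function of the record's polarity.  An association
    pair whose genome pair has no interaction record yields a grey edge typed
    ``unknown`` with a warning; an OTU without a match is shaded as identity 0.
    """
    identity = {m.otu_id: m.percent_identity for m in matches}
    genome_of = {m.otu_id: m.genome_id for m in matches}
    rec_of: dict[frozenset[str], InteractionRecord] = {
        frozenset(r.pair): r for r in records
    }

    nodes = [NetworkNode(otu, identity.get(otu, 0.0)) for otu in assoc.otu_ids()]
    edges: list[NetworkEdge] = []
    for otu_a, otu_b, weight in assoc:
        rec = None
        ga, gb = genome_of.get(otu_a), genome_of.get(otu_b)
        if ga is not None and gb is not None:
            rec = rec_of.get(frozenset((ga, gb)))
        if rec is None:
            logger.warning(
                "no interaction record for association (%s, %s); edge left grey",
                otu_a,
                otu_b,
            )
            edges.append(NetworkEdge(otu_a, otu_b, weight, "grey", "unknown"))
        else:
            edges.append(
                NetworkEdge(
                    otu_a, otu_b, weight, POLARITY_COLOR[rec.polarity], rec.type_label
                )
            )
    return InteractionNetwork(nodes=nodes, edges=edges)


def _to_nx(net: InteractionNetwork) -> nx.Graph:
    g = nx.Graph()
    for node in net.nodes:
        g.add_node(node.otu_id, identity=float(node.identity))
    for e in net.edges:
        g.add_edge(e.otu_a, e.otu_b, weight=float(e.weight), color=e.color, type=e.type_label)
    return g


def _json_payload(net: InteractionNetwork) -> dict:
    return {
        "nodes": [{"id": n.otu_id, "identity": n.identity} for n in net.nodes],
        "links": [
            {
                "source": e.otu_a,
                "target": e.otu_b,
                "weight": e.weight,
                "color": e.color,
                "type": e.type_label,
            }
            for e in net.edges
        ],
    }


def write_network(
    net: InteractionNetwork,
    formats: Iterable[str] = ("json", "graphml", "html"),
    outdir: str | Path = ".",
    basename: str = "network",
) -> dict[str, Path]:
    """Serialize the network; returns format → written path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    formats = set(formats)
    unknown = formats - {"json", "graphml", "html"}
    if unknown:
        raise ValueError(f"unknown network formats: {sorted(unknown)}")
    if "json" in formats:
        path = outdir / f"{basename}.json"
        path.write_text(json.dumps(_json_payload(net), indent=2) + "\n")
        paths["json"] = path
    if "graphml" in formats:
        path = outdir / f"{basename}.graphml"
        nx.write_graphml(_to_nx(net), path)
        paths["graphml"] = path
    if "html" in formats:
        path = outdir / f"{basename}.html"
        path.write_text(_render_html(net))
        paths["html"] = path
    return paths


def _render_html(net: InteractionNetwork, size: int = 640) -> str:
    """Self-contained HTML: embedded JSON plus a static SVG force layout.

    Layout is Fruchterman–Reingold with a fixed seed, so output bytes are
    reproducible.  Shorter/thicker edges for stronger associations are
    approximated by weighting the layout by association weight and scaling
    stroke width with weight.
    """
    g = _to_nx(net)
    if g.number_of_nodes() > 0:
        pos = nx.spring_layout(
            g, weight="weight", iterations=_LAYOUT_ITERATIONS, seed=_LAYOUT_SEED
        )
    else:
        pos = {}
    margin, span = 40, size - 80

    def xy(node: str) -> tuple[float, float]:
        x, y = pos[node]
        return margin + span * (x + 1) / 2, margin + span * (y + 1) / 2

    svg: list[str] = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{size}" height="{size}" '
        f'viewBox="0 0 {size} {size}">'
    ]
    max_w = max((abs(e.weight) for e in net.edges), default=1.0) or 1.0
    for e in net.edges:
        x1, y1 = xy(e.otu_a)
        x2, y2 = xy(e.otu_b)
        width = 0.5 + 3.0 * abs(e.weight) / max_w
        svg.append(
            f'<line x1="{x1:.1f}" y1="{y1:.1f}" x2="{x2:.1f}" y2="{y2:.1f}" '
            f'stroke="{e.color}" stroke-width="{width:.2f}">'
            f"<title>{_html.escape(e.type_label)}</title></line>"
        )
    for n in net.nodes:
        x, y = xy(n.otu_id)
        fill, dashed = node_shade(n.identity)
        dash = ' stroke-dasharray="3,2"' if dashed else ""
        svg.append(
            f'<circle cx="{x:.1f}" cy="{y:.1f}" r="9" fill="{fill}" '
            f'stroke="black" stroke-width="1"{dash}>'
            f"<title>{_html.escape(n.otu_id)} ({n.identity:.1f}%)</title></circle>"
        )
        svg.append(
            f'<text x="{x + 11:.1f}" y="{y + 4:.1f}" font-size="10" '
            f'font-family="sans-serif">{_html.escape(n.otu_id)}</text>'
        )
    svg.append("</svg>")

    payload = json.dumps(_json_payload(net), indent=2)
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        "<title>Predicted metabolic interaction network</title></head>\n<body>\n"
        "<h1>Predicted metabolic interaction network</h1>\n"
        "<p>Edges: green = positive interaction, red = negative, grey = none. "
        "Darker nodes = closer OTU-genome 16S match; dashed border = identity "
        "below 80%. Thicker edges = stronger association.</p>\n"
        + "\n".join(svg)
        + '\n<script type="application/json" id="network-data">\n'
        + payload
        + "\n</script>\n</body></html>\n"
    )
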