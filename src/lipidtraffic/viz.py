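"""Network pie-chart maps and wiring diagrams of a switch analysis.

Two signature renderings, both as deterministic text SVG:

* a **network map** — the tissue network with a small two-slice pie at each
  compartment (U-type counts, one slice per group), a larger pie on each
  edge (B-type counts), and ``J .. p ..`` annotations where an overlap
  result is supplied;
* a **wiring diagram** — one horizontal track per lipid variable and per
  group, with a stop glyph at every compartment where that group's presence
  holds (after the metro-map style of route diagrams).

All counts are taken directly from the classification structures, never
recomputed, and every plotted number is also written to a JSON sidecar.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .nomenclature import LipidSpecies, sort_key
from .network import TissueNetwork, edge_key
from .overlap import OverlapResult
from .switch import SwitchClassification

__all__ = [
    "GROUP_COLOURS",
    "NetworkFigureSpec",
    "build_switch_figure",
    "render_switch_svg",
    "WiringDiagram",
    "build_wiring_diagram",
    "render_wiring_svg",
]

#: default colours: blue = group 1 (control/lean), orange = group 2 (case)
GROUP_COLOURS = ("#1f77b4", "#ff7f0e")


def _layout(network: TissueNetwork) -> dict[str, tuple[float, float]]:
    """Deterministic layout: the highest-degree compartment at the centre,
    the rest on a circle in sorted order."""
    degree = {c: len(network.neighbours(c)) for c in network.compartments}
    hub = max(sorted(network.compartments), key=lambda c: degree[c])
    rim = sorted(c for c in network.compartments if c != hub)
    pos = {hub: (0.0, 0.0)}
    for i, c in enumerate(rim):
        angle = 2 * math.pi * i / len(rim) - math.pi / 2
        pos[c] = (round(math.cos(angle), 6), round(math.sin(angle), 6))
    return pos


@dataclass
class NetworkFigureSpec:
    """Everything needed to render the network map, as plain numbers."""

    positions: dict[str, tuple[float, float]]
    node_counts: dict[str, tuple[int, int]]  # compartment -> (U_g1, U_g2)
    edge_counts: dict[tuple[str, str], tuple[int, int]]  # edge -> (B_g1, B_g2)
    annotations: dict[str, str]  # location label -> "J .. p .." text
    groups: tuple[str, str]
    colours: tuple[str, str] = GROUP_COLOURS

    def to_json_dict(self) -> dict:
        return {
            "groups": list(self.groups),
            "node_counts": {c: list(v) for c, v in self.node_counts.items()},
            "edge_counts": {
                f"{a}-{b}": list(v) for (a, b), v in self.edge_counts.items()
            },
            "annotations": dict(self.annotations),
        }


def build_switch_figure(
    class_g1: SwitchClassification,
    class_g2: SwitchClassification,
    network: TissueNetwork,
    overlaps: Mapping[str, OverlapResult] | None = None,
    colours: tuple[str, str] = GROUP_COLOURS,
) -> NetworkFigureSpec:
    """Assemble the network-map figure spec from one run's results.

    ``overlaps`` maps a location label (a compartment for U scopes, an
    ``"a-b"`` edge label for B scopes) to its overlap result; annotations
    are formatted to 2 decimals.
    """
    for cls in (class_g1, class_g2):
        if cls.network != network:
            raise ValueError("classification/network mismatch")
    node_counts = {
        c: (len(class_g1.u_lists[c]), len(class_g2.u_lists[c]))
        for c in network.compartments
    }
    edge_counts = {
        e: (len(class_g1.b_lists[e]), len(class_g2.b_lists[e]))
        for e in (edge_key(*e) for e in network.edges)
    }
    annotations = {}
    for label, res in (overlaps or {}).items():
        known = set(network.compartments) | {f"{a}-{b}" for a, b in network.edges}
        if label not in known:
            raise ValueError(f"overlap annotation for unknown location {label!r}")
        annotations[label] = res.display()
    return NetworkFigureSpec(
        positions=_layout(network),
        node_counts=node_counts,
        edge_counts=edge_counts,
        annotations=annotations,
        groups=(class_g1.group, class_g2.group),
        colours=colours,
    )


def _pie(cx: float, cy: float, r: float, counts: tuple[int, int],
         colours: tuple[str, str]) -> list[str]:
    """A two-slice pie; a zero total becomes an annotated empty circle."""
    total = counts[0] + counts[1]
    out = []
    if total == 0:
        out.append(
            f'<circle cx="{cx:.1f}" cy="{cy:.1f}" r="{r:.1f}" fill="none" '
            f'stroke="#999" stroke-dasharray="2,2"/>'
        )
        out.append(
            f'<text x="{cx:.1f}" y="{cy + 4:.1f}" text-anchor="middle" '
            f'font-size="10">0</text>'
        )
        return out
    frac = counts[0] / total
    if frac in (0.0, 1.0):
        fill = colours[0] if frac == 1.0 else colours[1]
        out.append(
            f'<circle cx="{cx:.1f}" cy="{cy:.1f}" r="{r:.1f}" fill="{fill}"/>'
        )
    else:
        angle = 2 * math.pi * frac
        x1, y1 = cx, cy - r
        x2 = cx + r * math.sin(angle)
        y2 = cy - r * math.cos(angle)
        large = 1 if frac > 0.5 else 0
        out.append(
            f'<path d="M{cx:.1f},{cy:.1f} L{x1:.1f},{y1:.1f} '
            f'A{r:.1f},{r:.1f} 0 {large} 1 {x2:.2f},{y2:.2f} Z" '
            f'fill="{colours[0]}"/>'
        )
        out.append(
            f'<path d="M{cx:.1f},{cy:.1f} L{x2:.2f},{y2:.2f} '
            f'A{r:.1f},{r:.1f} 0 {1 - large} 1 {x1:.1f},{y1:.1f} Z" '
            f'fill="{colours[1]}"/>'
        )
    out.append(
        f'<text x="{cx:.1f}" y="{cy - r - 4:.1f}" text-anchor="middle" '
        f'font-size="10">{counts[0]}:{counts[1]}</text>'
    )
    return out


def render_switch_svg(
    spec: NetworkFigureSpec, path: str | Path, *, size: int = 640
) -> None:
    """Write the network map as an SVG file plus a JSON sidecar."""
    scale = size * 0.36
    cx0 = cy0 = size / 2

    def xy(c: str) -> tuple[float, float]:
        x, y = spec.positions[c]
        return cx0 + scale * x, cy0 + scale * y

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{size}" '
        f'height="{size}" font-family="sans-serif">'
    ]
    for (a, b), counts in sorted(spec.edge_counts.items()):
        xa, ya = xy(a)
        xb, yb = xy(b)
        parts.append(
            f'<line x1="{xa:.1f}" y1="{ya:.1f}" x2="{xb:.1f}" y2="{yb:.1f}" '
            f'stroke="#555" stroke-width="2"/>'
        )
    for (a, b), counts in sorted(spec.edge_counts.items()):
        xa, ya = xy(a)
        xb, yb = xy(b)
        mx, my = (xa + xb) / 2, (ya + yb) / 2
        parts += _pie(mx, my, 26.0, counts, spec.colours)
        note = spec.annotations.get(f"{a}-{b}")
        if note:
            parts.append(
                f'<text x="{mx:.1f}" y="{my + 40:.1f}" text-anchor="middle" '
                f'font-size="10">{note}</text>'
            )
    for c in sorted(spec.node_counts):
        x, y = xy(c)
        parts += _pie(x, y, 14.0, spec.node_counts[c], spec.colours)
        parts.append(
            f'<text x="{x:.1f}" y="{y + 30:.1f}" text-anchor="middle" '
            f'font-size="12" font-weight="bold">{c}</text>'
        )
        note = spec.annotations.get(c)
        if note:
            parts.append(
                f'<text x="{x:.1f}" y="{y + 44:.1f}" text-anchor="middle" '
                f'font-size="10">{note}</text>'
            )
    for i, g in enumerate(spec.groups):
        parts.append(
            f'<rect x="10" y="{10 + 18 * i}" width="12" height="12" '
            f'fill="{spec.colours[i]}"/>'
        )
        parts.append(
            f'<text x="28" y="{20 + 18 * i}" font-size="12">{g}</text>'
        )
    parts.append("</svg>")
    path = Path(path)
    path.write_text("\n".join(parts) + "\n")
    path.with_suffix(".json").write_text(
        json.dumps(spec.to_json_dict(), indent=2, sort_keys=True) + "\n"
    )


@dataclass
class WiringDiagram:
    """One track per (variable, group); stops where presence holds."""

    variables: list[str]  # canonical order
    compartments: list[str]
    stops: dict[tuple[str, str], tuple[str, ...]]  # (variable, group) -> comps
    groups: tuple[str, str]
    colours: tuple[str, str] = GROUP_COLOURS

    def to_json_dict(self) -> dict:
        return {
            "groups": list(self.groups),
            "compartments": self.compartments,
            "stops": {
                f"{v}|{g}": list(s) for (v, g), s in sorted(self.stops.items())
            },
        }


def build_wiring_diagram(
    class_g1: SwitchClassification,
    class_g2: SwitchClassification,
    network: TissueNetwork,
    subset: list[str] | None = None,
    species: Mapping[str, LipidSpecies] | None = None,
) -> WiringDiagram:
    """Assemble a wiring diagram for a subset of variables.

    ``subset`` defaults to every variable detected in either group;
    unknown names raise.  Variables are ordered canonically when ``species``
    records are supplied, alphabetically otherwise.
    """
    records = {**class_g1.records}
    if subset is None:
        subset = sorted(
            v for v, r in records.items()
            if r.present_compartments or class_g2.records[v].present_compartments
        )
    if not subset:
        raise ValueError("empty variable subset: nothing to draw")
    unknown = [v for v in subset if v not in records or v not in class_g2.records]
    if unknown:
        raise ValueError(f"unknown variables in subset: {unknown}")
    if species:
        variables = sorted(subset, key=lambda v: sort_key(species[v]))
    else:
        variables = sorted(subset)
    comps = list(network.compartments)
    stops = {}
    for v in variables:
        for g, cls in ((class_g1.group, class_g1), (class_g2.group, class_g2)):
            present = cls.records[v].present_compartments
            stops[(v, g)] = tuple(c for c in comps if c in present)
    return WiringDiagram(
        variables=variables,
        compartments=comps,
        groups=(class_g1.group, class_g2.group),
        stops=stops,
    )


def render_wiring_svg(diagram: WiringDiagram, path: str | Path) -> None:
    """Write the wiring diagram as an SVG file plus a JSON sidecar."""
    left, top, col_w, row_h = 140, 40, 70, 26
    width = left + col_w * len(diagram.compartments) + 20
    height = top + row_h * len(diagram.variables) + 20
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" font-family="sans-serif">'
    ]
    for ci, c in enumerate(diagram.compartments):
        parts.append(
            f'<text x="{left + col_w * ci}" y="{top - 16}" font-size="11" '
            f'text-anchor="middle" transform="rotate(-30 '
            f'{left + col_w * ci} {top - 16})">{c}</text>'
        )
    for vi, v in enumerate(diagram.variables):
        y0 = top + row_h * vi
        parts.append(
            f'<text x="{left - 10}" y="{y0 + 8}" font-size="11" '
            f'text-anchor="end">{v}</text>'
        )
        for gi, g in enumerate(diagram.groups):
            y = y0 + 5 * gi
            colour = diagram.colours[gi]
            stop_set = diagram.stops[(v, g)]
            if stop_set:
                xs = [
                    left + col_w * diagram.compartments.index(c) for c in stop_set
                ]
                parts.append(
                    f'<line x1="{min(xs)}" y1="{y}" x2="{max(xs)}" y2="{y}" '
                    f'stroke="{colour}" stroke-width="3"/>'
                )
                for x in xs:
                    parts.append(
                        f'<circle cx="{x}" cy="{y}" r="4" fill="white" '
                        f'stroke="{colour}" stroke-width="2"/>'
                    )
    parts.append("</svg>")
    path = Path(path)
    path.write_text("\n".join(parts) + "\n")
    path.with_suffix(".json").write_text(
        json.dumps(diagram.to_json_dict(), indent=2, sort_keys=True) + "\n"
    )
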