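"""Imbalance clone plots as graphs.

Nuclei are grouped by their gain/loss pattern (not raw counts), so
signal patterns that differ only in the magnitude of the same imbalance
collapse into one clone.  Clones one single-step change apart (a gene
moving between neutral and gain, or neutral and loss) are connected by
a directed edge pointing from the clone with fewer aberrant genes to
the one with more; a switch from loss to gain passes through neutral
and therefore counts as two changes.  The result is a DAG whose sources
are the least-aberrant clones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .clonal import GainLossPattern, annotate_ploidy, gain_loss_pattern
from .io import NucleusRecord
from .panel import ProbePanel

_STATE_RANK = {"loss": -1, "neutral": 0, "gain": 1}


@dataclass(frozen=True)
class CloneNode:
    pattern: GainLossPattern
    frequency: float


@dataclass
class CloneGraph:
    nodes: list[CloneNode]
    edges: list[tuple[int, int]]  # indices into nodes, parent -> child
    gene_names: list[str]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for i, node in enumerate(self.nodes):
            g.add_node(
                i,
                pattern=node.pattern.label(self.gene_names),
                frequency=node.frequency,
                n_aberrant=node.pattern.n_aberrant,
            )
        g.add_edges_from(self.edges)
        return g

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))

    def write_dot(self, path: str | Path) -> None:
        lines = ["digraph clones {"]
        for i, node in enumerate(self.nodes):
            label = f"{node.pattern.label(self.gene_names)}\\n{node.frequency:.1%}"
            lines.append(f'  n{i} [label="{label}"];')
        for a, b in self.edges:
            lines.append(f"  n{a} -> n{b};")
        lines.append("}")
        Path(path).write_text("\n".join(lines) + "\n")


def is_single_step(a: GainLossPattern, b: GainLossPattern) -> bool:
    """True iff the patterns differ at exactly one gene by one step
    (neutral<->gain or neutral<->loss; loss<->gain is two steps)."""
    diffs = [
        (sa, sb) for sa, sb in zip(a.states, b.states) if sa != sb
    ]
    if len(diffs) != 1:
        return False
    sa, sb = diffs[0]
    return abs(_STATE_RANK[sa] - _STATE_RANK[sb]) == 1


def build_clone_graph(
    records: list[NucleusRecord],
    panel: ProbePanel,
    include_centromeres_in_mean: bool = True,
) -> CloneGraph:
    """Group nuclei into gain/loss clones and connect single-step pairs."""
    if not records:
        raise ValueError("build_clone_graph: empty input")
    counter: dict[tuple[str, ...], int] = {}
    for r in records:
        ann = annotate_ploidy(r.counts, panel, include_centromeres_in_mean)
        glp = gain_loss_pattern(r.counts, ann.nucleus_ploidy, panel)
        counter[glp.states] = counter.get(glp.states, 0) + 1
    n = len(records)
    ordered = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    nodes = [CloneNode(GainLossPattern(states), mult / n) for states, mult in ordered]
    edges = []
    for i, a in enumerate(nodes):
        for j, b in enumerate(nodes):
            if i == j:
                continue
            if (
                a.pattern.n_aberrant < b.pattern.n_aberrant
                and is_single_step(a.pattern, b.pattern)
            ):
                edges.append((i, j))
    return CloneGraph(nodes, edges, panel.gene_names)
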