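"""Recruitment forests: who recruited whom.

The recruitment history of a chain-referral survey is a directed forest —
every participant has at most one recruiter, recruiters hand out at most
``MAX_COUPONS`` invitations, and each tree is rooted at a seed chosen by the
researchers.  ``wave`` is the number of recruitment steps from the seed.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .records import ParticipantRecord

#: Invitation limit per respondent.
MAX_COUPONS = 4


@dataclass
class RecruitmentForest:
    """Directed forest of recruiter -> recruited edges.

    ``wave`` maps each pid to its recruitment depth (seeds are wave 0) and
    ``component_id`` labels each weakly connected component by its smallest
    member pid, so labels are deterministic across row orders.
    """

    graph: nx.DiGraph
    wave: dict = field(default_factory=dict)
    component_id: dict = field(default_factory=dict)

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def seeds(self) -> list:
        return sorted(n for n in self.graph.nodes if self.graph.in_degree(n) == 0)

    def components(self) -> dict:
        """Component label -> sorted list of member pids."""
        out: dict[str, list] = {}
        for pid, label in self.component_id.items():
            out.setdefault(label, []).append(pid)
        for members in out.values():
            members.sort()
        return out

    def recruiter_of(self, pid) -> Optional[str]:
        preds = list(self.graph.predecessors(pid))
        return preds[0] if preds else None

    def max_wave(self) -> int:
        return max(self.wave.values()) if self.wave else 0

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def build_forest(
    records: Iterable[ParticipantRecord],
    *,
    lenient_orphans: bool = False,
    max_coupons: int = MAX_COUPONS,
) -> RecruitmentForest:
    """Reconstruct the recruitment forest from participant records.

    Parameters
    ----------
    records
        Validated participant records (unique pids).
    lenient_orphans
        A recruiter_pid that matches no record is a hard error by default;
        under the lenient flag the orphan is demoted to a seed instead.
    max_coupons
        Out-degree limit; recruiters exceeding it are a hard error.

    The result is independent of the input row order.
    """
    records = list(records)
    pids = {r.pid for r in records}
    if len(pids) != len(records):
        from .records import validate_unique_pids

        validate_unique_pids(records)

    g = nx.DiGraph()
    g.add_nodes_from(sorted(pids))
    orphans = []
    for rec in sorted(records, key=lambda r: r.pid):
        if rec.recruiter_pid is None:
            continue
        if rec.recruiter_pid not in pids:
            if lenient_orphans:
                orphans.append(rec.pid)
                continue
            raise ValueError(
                f"recruiter_pid {rec.recruiter_pid!r} of {rec.pid!r} "
                "matches no participant (pass lenient_orphans=True to demote "
                "such records to seeds)"
            )
        if rec.recruiter_pid == rec.pid:
            raise ValueError(f"cycle detected: {rec.pid} -> {rec.pid}")
        g.add_edge(rec.recruiter_pid, rec.pid)

    if orphans:
        import warnings

        warnings.warn(
            f"{len(orphans)} record(s) with unknown recruiter demoted to seeds: "
            f"{', '.join(sorted(orphans))}",
            stacklevel=2,
        )

    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"cycle detected: {cycle}")
    over = sorted(n for n in g.nodes if g.out_degree(n) > max_coupons)
    if over:
        raise ValueError(
            f"recruiter(s) exceed the {max_coupons}-coupon limit: {', '.join(over)}"
        )
    bad_in = sorted(n for n in g.nodes if g.in_degree(n) > 1)
    if bad_in:  # unreachable when records are well-formed (one recruiter field)
        raise ValueError(f"node(s) with multiple recruiters: {', '.join(bad_in)}")

    wave: dict[str, int] = {}
    for seed in (n for n in g.nodes if g.in_degree(n) == 0):
        wave[seed] = 0
        queue = deque([seed])
        while queue:
            parent = queue.popleft()
            for child in g.successors(parent):
                wave[child] = wave[parent] + 1
                queue.append(child)

    component_id: dict[str, str] = {}
    for comp in nx.weakly_connected_components(g):
        label = min(comp)
        for pid in comp:
            component_id[pid] = label

    return RecruitmentForest(graph=g, wave=wave, component_id=component_id)


def export_forest(
    forest: RecruitmentForest,
    fmt: str,
    records: Optional[Iterable[ParticipantRecord]] = None,
) -> str:
    """Serialize a forest as GraphML or DOT text.

    When ``records`` are given, ``age``, ``gender``, ``education`` and
    ``is_seed`` are attached as node attributes (missing values omitted so
    the output stays parseable by standard graph tooling).
    """
    if fmt not in ("graphml", "dot"):
        raise ValueError(f"unknown export format {fmt!r}; use 'graphml' or 'dot'")

    g = nx.DiGraph()
    g.add_nodes_from(forest.graph.nodes)
    g.add_edges_from(forest.graph.edges)
    by_pid = {r.pid: r for r in records} if records is not None else {}
    for node in g.nodes:
        attrs = {"is_seed": forest.graph.in_degree(node) == 0}
        rec = by_pid.get(node)
        if rec is not None:
            if rec.age is not None:
                attrs["age"] = int(rec.age)
            if rec.gender is not None:
                attrs["gender"] = rec.gender
            if rec.education is not None:
                attrs["education"] = rec.education
        g.nodes[node].update(attrs)

    if fmt == "graphml":
        return "\n".join(nx.generate_graphml(g))

    lines = ["digraph recruitment {"]
    for node in sorted(g.nodes):
        attrs = g.nodes[node]
        label = ",".join(f'{k}="{v}"' for k, v in sorted(attrs.items()))
        lines.append(f'  "{node}" [{label}];' if label else f'  "{node}";')
    for u, v in sorted(g.edges):
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines)


def import_graphml(text: str) -> RecruitmentForest:
    """Parse a GraphML export back into a forest (round-trip helper)."""
    g = nx.parse_graphml(text)
    edges = [(u, v) for u, v in g.edges]
    recs = [
        ParticipantRecord(pid=str(n), recruiter_pid=None) for n in g.nodes
    ]
    by_pid = {r.pid: r for r in recs}
    for u, v in edges:
        by_pid[str(v)] = by_pid[str(v)].copy(recruiter_pid=str(u))
    return build_forest(by_pid.values())
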