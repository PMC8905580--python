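"""Aggregate detection, size dynamics, transition networks, events and CAP.

Two molecules are in the same aggregate when any of their atoms lie within a
contact cutoff (default 0.5 nm, minimum-image).  Aggregates per frame are the
single-linkage connected components of that molecule contact graph.  From the
per-frame partitions we derive:

* nonaggregated fractions — percent of molecules in aggregates smaller than a
  cutoff size n (n = 2 counts only free monomers as nonaggregated);
* transition networks — directed graphs whose nodes are aggregate sizes and
  whose edges count observed size-to-size transitions between consecutive
  frames, aggregates tracked by maximal membership overlap;
* binding/unbinding event logs per molecule pair, with an optional debounce
  so that flickering contacts can be filtered;
* the collision acceptance probability CAP = (n_bind - n_unbind) / n_bind
  (clipped to [0, 1]) — near 1 when almost every collision leads to a lasting
  contact (aggregation-prone), near 0 when binding is routinely reversed.
  The alternative estimator n_bind / (n_bind + n_unbind) is selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .model import Frame, Topology, Trajectory, molecule_contact_matrix

__all__ = [
    "AggregateState",
    "TransitionNetwork",
    "EventLog",
    "assign_aggregates",
    "aggregate_states",
    "nonaggregated_fraction",
    "build_transition_network",
    "detect_events",
    "collision_acceptance_probability",
]


@dataclass
class AggregateState:
    """Partition of the molecules of one frame into aggregates.

    ``aggregates`` are disjoint, jointly exhaustive tuples of molecule
    indices, each sorted, the list ordered by smallest member index.
    """

    frame_time: float
    aggregates: list[tuple[int, ...]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for agg in self.aggregates:
            if not agg:
                raise ValueError("empty aggregate")
            if seen & set(agg):
                raise ValueError("aggregates must be disjoint")
            seen |= set(agg)

    @property
    def sizes(self) -> list[int]:
        return [len(a) for a in self.aggregates]

    @property
    def n_molecules(self) -> int:
        return sum(self.sizes)


def assign_aggregates(frame: Frame, topology: Topology,
                      cutoff: float = 0.5) -> AggregateState:
    """Single-linkage aggregates of one frame.

    Connected components of the molecule contact graph (edge iff the
    molecule-molecule minimum atom distance is <= ``cutoff`` nm, minimum
    image).  Output ordering is deterministic: members sorted within each
    aggregate, aggregates sorted by smallest member.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    contact = molecule_contact_matrix(frame, topology, cutoff)
    n_comp, labels = connected_components(csr_matrix(contact), directed=False)
    groups: dict[int, list[int]] = {}
    for mol, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(mol)
    aggs = sorted((tuple(sorted(g)) for g in groups.values()),
                  key=lambda a: a[0])
    return AggregateState(frame.time, aggs)


def aggregate_states(traj: Trajectory, cutoff: float = 0.5,
                     stride: int = 1) -> list[AggregateState]:
    """Aggregate partition of every (strided) frame."""
    return [assign_aggregates(f, traj.topology, cutoff)
            for f in traj.strided(stride).frames]


def nonaggregated_fraction(traj: Trajectory, cutoff_size: int,
                           contact_cutoff: float = 0.5,
                           stride: int = 1,
                           states: list[AggregateState] | None = None,
                           ) -> pd.DataFrame:
    """Percent of molecules residing in aggregates of size < ``cutoff_size``.

    With ``cutoff_size`` n = 2 only free monomers count as nonaggregated;
    with n = 10 all oligomers below the 10-mer do.  Returns a frame with
    columns ``time_ns`` and ``percent``.  Pass precomputed ``states`` to
    avoid re-clustering when sweeping n.
    """
    if cutoff_size < 2:
        raise ValueError("cutoff_size must be >= 2")
    if states is None:
        states = aggregate_states(traj, contact_cutoff, stride)
    rows = []
    for st in states:
        n_mol = st.n_molecules
        free = sum(s for s in st.sizes if s < cutoff_size)
        rows.append({"time_ns": st.frame_time,
                     "percent": 100.0 * free / n_mol})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# transition networks


@dataclass
class TransitionNetwork:
    """Size-to-size transition statistics of the aggregation process.

    ``nodes`` maps aggregate size -> occupancy count (total observations of
    an aggregate with that size across all frames); ``edges`` maps
    (size_from, size_to) -> number of observed transitions.  Same-size
    transitions are occupancy, not edges.
    """

    nodes: dict[int, int] = field(default_factory=dict)
    edges: dict[tuple[int, int], int] = field(default_factory=dict)

    @property
    def max_size(self) -> int:
        return max(self.nodes) if self.nodes else 0

    def to_networkx(self):
        """Directed graph with ``occupancy`` node and ``count`` edge attributes."""
        import networkx as nx

        g = nx.DiGraph()
        for size, occ in sorted(self.nodes.items()):
            g.add_node(size, occupancy=occ)
        for (si, sj), cnt in sorted(self.edges.items()):
            g.add_edge(si, sj, count=cnt)
        return g

    def edge_table(self) -> pd.DataFrame:
        rows = [{"size_from": si, "size_to": sj, "count": c}
                for (si, sj), c in sorted(self.edges.items())]
        return pd.DataFrame(rows, columns=["size_from", "size_to", "count"])

    def growth_path_connected(self) -> bool:
        """True if node 1 reaches the largest node through the undirected edges."""
        import networkx as nx

        if not self.nodes:
            return False
        if self.max_size == 1:
            return True
        g = self.to_networkx().to_undirected()
        return (1 in g and self.max_size in g
                and nx.has_path(g, 1, self.max_size))


def _match_aggregate(agg: tuple[int, ...],
                     nxt: list[tuple[int, ...]]) -> tuple[int, ...]:
    """Aggregate of the next frame with maximal membership overlap.

    Ties break toward the smaller target, then the smallest member index.
    Partitions cover the same molecules, so the best overlap is >= 1.
    """
    a = set(agg)
    best = max(nxt, key=lambda b: (len(a & set(b)), -len(b), -b[0]))
    return best


def build_transition_network(states: list[AggregateState]) -> TransitionNetwork:
    """Track aggregates across consecutive frames and count size changes.

    Each aggregate of frame t is matched to the aggregate of frame t+1 with
    which it shares the most molecules; a match with a different size adds
    one count to the (size_t -> size_t+1) edge.  Node occupancancies count
    every aggregate observation, so newly appearing aggregates enter the
    network even when nothing transitions into them.
    """
    if len(states) < 2:
        raise ValueError("need at least 2 states to build a network")
    net = TransitionNetwork()
    for st in states:
        for agg in st.aggregates:
            net.nodes[len(agg)] = net.nodes.get(len(agg), 0) + 1
    for prev, nxt in zip(states[:-1], states[1:]):
        for agg in prev.aggregates:
            target = _match_aggregate(agg, nxt.aggregates)
            if len(target) != len(agg):
                key = (len(agg), len(target))
                net.edges[key] = net.edges.get(key, 0) + 1
    return net


# ---------------------------------------------------------------------------
# binding/unbinding events and CAP


@dataclass
class EventLog:
    """Per-pair binding/unbinding events of one trajectory.

    ``events`` holds (pair, frame_time, kind) with kind in {"bind",
    "unbind"}; per pair the kinds alternate, the first event being the first
    settled departure from that pair's initial settled contact status.
    ``initial_bound`` / ``final_bound`` are the settled bound-pair sets of
    the first and last frame, which ties event counts to the net change:
    n_bind - n_unbind == len(final_bound) - len(initial_bound).
    """

    events: list[tuple[tuple[int, int], float, str]] = field(default_factory=list)
    initial_bound: set[tuple[int, int]] = field(default_factory=set)
    final_bound: set[tuple[int, int]] = field(default_factory=set)

    @property
    def n_bind(self) -> int:
        return sum(1 for *_, kind in self.events if kind == "bind")

    @property
    def n_unbind(self) -> int:
        return sum(1 for *_, kind in self.events if kind == "unbind")

    def to_table(self) -> pd.DataFrame:
        rows = [{"mol_i": p[0], "mol_j": p[1], "time_ns": t, "kind": k}
                for p, t, k in self.events]
        return pd.DataFrame(rows, columns=["mol_i", "mol_j", "time_ns", "kind"])

    def windowed_counts(self, window_ns: float) -> pd.DataFrame:
        """Bind/unbind counts binned into fixed time windows."""
        df = self.to_table()
        if df.empty:
            return pd.DataFrame(columns=["window_start_ns", "bind", "unbind"])
        start = df["time_ns"].min()
        df["window_start_ns"] = (
            ((df["time_ns"] - start) // window_ns) * window_ns + start
        )
        out = (df.groupby(["window_start_ns", "kind"]).size()
               .unstack(fill_value=0).reset_index())
        for col in ("bind", "unbind"):
            if col not in out:
                out[col] = 0
        return out[["window_start_ns", "bind", "unbind"]]


def _debounced_events(status: np.ndarray, times: np.ndarray,
                      debounce: int) -> tuple[list[tuple[float, str]], bool, bool]:
    """Events of one pair's contact time series under a persistence filter.

    The settled state starts as the first frame's status; a change of status
    becomes an event only when the new status persists for at least
    ``debounce`` consecutive frames.  Returns (events, settled_initial,
    settled_final).
    """
    settled = bool(status[0])
    initial = settled
    events: list[tuple[float, str]] = []
    n = status.size
    i = 1
    while i < n:
        s = bool(status[i])
        if s == settled:
            i += 1
            continue
        j = i
        while j + 1 < n and bool(status[j + 1]) == s:
            j += 1
        run = j - i + 1
        if run >= debounce:
            events.append((float(times[i]), "bind" if s else "unbind"))
            settled = s
        i = j + 1
    return events, initial, settled


def detect_events(traj: Trajectory, contact_cutoff: float = 0.5,
                  debounce: int = 1, stride: int = 1) -> EventLog:
    """Binding/unbinding events for every molecule pair.

    A pair's contact status per frame is 1 when the molecules' minimum atom
    distance is within ``contact_cutoff``.  A status change counts as an
    event only if the new status persists for at least ``debounce`` frames
    (default 1 = every raw transition).  Per pair, bind and unbind strictly
    alternate relative to the pair's initial settled status.
    """
    if debounce < 1:
        raise ValueError("debounce must be >= 1")
    frames = traj.strided(stride).frames
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to detect events")
    n = traj.topology.n_molecules
    times = np.array([f.time for f in frames])
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    status = np.zeros((len(frames), len(pairs)), dtype=bool)
    for fi, f in enumerate(frames):
        contact = molecule_contact_matrix(f, traj.topology, contact_cutoff)
        status[fi] = [contact[i, j] for (i, j) in pairs]

    log = EventLog()
    all_events: list[tuple[tuple[int, int], float, str]] = []
    for pi, pair in enumerate(pairs):
        events, init, final = _debounced_events(status[:, pi], times, debounce)
        for t, kind in events:
            all_events.append((pair, t, kind))
        if init:
            log.initial_bound.add(pair)
        if final:
            log.final_bound.add(pair)
    all_events.sort(key=lambda e: (e[1], e[0]))
    log.events = all_events
    return log


def collision_acceptance_probability(log: EventLog,
                                     formula: str = "net") -> float:
    """CAP from an event log.

    ``formula="net"`` (default): (n_bind - n_unbind) / n_bind clipped to
    [0, 1] — 1 for irreversible binding, 0 when every binding event is
    eventually reversed.  ``formula="ratio"``: n_bind / (n_bind + n_unbind),
    an alternative with the same limits.
    """
    b, u = log.n_bind, log.n_unbind
    if b == 0:
        raise ValueError("CAP undefined: no binding events observed")
    if formula == "net":
        return float(np.clip((b - u) / b, 0.0, 1.0))
    if formula == "ratio":
        return b / (b + u)
    raise ValueError(f"unknown CAP formula {formula!r}")
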