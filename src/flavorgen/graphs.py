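"""Molecular graphs as editable action targets.

A molecule is represented as an ordered list of heavy atoms (element symbol,
formal charge) plus a set of bonds with integer order 1-3.  Hydrogens are
implicit and aromatic systems are kekulized on input, so the bond vocabulary
stays {single, double, triple}; RDKit re-aromatizes on canonical SMILES
emission.  Graphs are grown from the empty graph by three action kinds --
adding a node, connecting two existing nodes, or terminating -- which is the
state/action space the generative model operates on.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

from rdkit import Chem, RDLogger

from .errors import (
    ContractError,
    InvalidActionError,
    UnsupportedInputError,
    ValidityError,
)

RDLogger.DisableLog("rdApp.*")

BOND_ORDERS = (1, 2, 3)
CHARGES = (-1, 0, 1)

_RD_BOND = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}

# Maximum total bond order per (element, charge).  RDKit sanitization remains
# the final authority in is_valid(); this table only gates action application.
VALENCE_CAPS: dict[tuple[str, int], int] = {
    ("C", 0): 4, ("C", -1): 3, ("C", 1): 3,
    ("N", 0): 3, ("N", 1): 4, ("N", -1): 2,
    ("O", 0): 2, ("O", 1): 3, ("O", -1): 1,
    ("S", 0): 6, ("S", 1): 3, ("S", -1): 1,
    ("P", 0): 5, ("F", 0): 1, ("Cl", 0): 1, ("Br", 0): 1, ("I", 0): 1,
}


def valence_cap(element: str, charge: int) -> int:
    try:
        return VALENCE_CAPS[(element, charge)]
    except KeyError:
        pt = Chem.GetPeriodicTable()
        try:
            return max(1, pt.GetDefaultValence(element) + charge)
        except Exception as exc:  # unknown element symbol
            raise ValidityError(f"unknown element {element!r}") from exc


class ActionKind(Enum):
    ADD = "add"
    CONNECT = "connect"
    TERMINATE = "terminate"


@dataclass(frozen=True)
class Action:
    """One graph-building move.

    ADD carries (attach_to index or None for the first atom, element, charge,
    bond order; bond order is ignored when attach_to is None).  CONNECT
    carries (i, j, bond order).  TERMINATE carries nothing.
    """

    kind: ActionKind
    attach_to: Optional[int] = None
    element: Optional[str] = None
    charge: int = 0
    bond_order: Optional[int] = None
    i: Optional[int] = None
    j: Optional[int] = None

    @staticmethod
    def add(attach_to: Optional[int], element: str, charge: int = 0,
            bond_order: Optional[int] = 1) -> "Action":
        return Action(ActionKind.ADD, attach_to=attach_to, element=element,
                      charge=charge, bond_order=bond_order)

    @staticmethod
    def connect(i: int, j: int, bond_order: int) -> "Action":
        return Action(ActionKind.CONNECT, i=i, j=j, bond_order=bond_order)

    @staticmethod
    def terminate() -> "Action":
        return Action(ActionKind.TERMINATE)


@dataclass
class MolecularGraph:
    """Ordered heavy-atom graph with kekulized integer bond orders."""

    nodes: list[tuple[str, int]] = field(default_factory=list)
    edges: set[tuple[int, int, int]] = field(default_factory=set)  # (i, j, order), i < j
    terminated: bool = False

    def __post_init__(self) -> None:
        n = len(self.nodes)
        for i, j, order in self.edges:
            if not (0 <= i < j < n):
                raise ValidityError(f"edge ({i},{j}) out of range or unordered")
            if order not in BOND_ORDERS:
                raise ValidityError(f"bond order {order} not in {BOND_ORDERS}")
        pairs = {(i, j) for i, j, _ in self.edges}
        if len(pairs) != len(self.edges):
            raise ValidityError("duplicate edge between a node pair")

    # -- queries -----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def used_valence(self, idx: int) -> int:
        return sum(order for i, j, order in self.edges if idx in (i, j))

    def free_valence(self, idx: int) -> int:
        element, charge = self.nodes[idx]
        return valence_cap(element, charge) - self.used_valence(idx)

    def neighbors(self, idx: int) -> list[tuple[int, int]]:
        """(neighbor index, bond order) pairs."""
        out = []
        for i, j, order in self.edges:
            if i == idx:
                out.append((j, order))
            elif j == idx:
                out.append((i, order))
        return sorted(out)

    def is_connected(self) -> bool:
        if self.n_nodes == 0:
            return False
        seen = {0}
        queue = deque([0])
        adj: dict[int, list[int]] = {k: [] for k in range(self.n_nodes)}
        for i, j, _ in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        while queue:
            v = queue.popleft()
            for w in adj[v]:
                if w not in seen:
                    seen.add(w)
                    queue.append(w)
        return len(seen) == self.n_nodes

    def copy(self) -> "MolecularGraph":
        return MolecularGraph(list(self.nodes), set(self.edges), self.terminated)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MolecularGraph):
            return NotImplemented
        return (self.nodes == other.nodes and self.edges == other.edges
                and self.terminated == other.terminated)


@dataclass
class DecodingRoute:
    """Canonical action sequence that rebuilds a molecule from scratch.

    ``steps[k]`` holds the partial graph *before* the k-th action is applied;
    the last action is always TERMINATE and replaying every action from the
    empty graph reproduces ``final`` exactly, node order included.
    """

    steps: list[tuple[MolecularGraph, Action]]
    final: MolecularGraph

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def actions(self) -> list[Action]:
        return [a for _, a in self.steps]


# ---------------------------------------------------------------------------
# SMILES I/O
# ---------------------------------------------------------------------------

def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a terminated, kekulized heavy-atom graph."""
    if not smiles or not smiles.strip():
        raise ValidityError("empty SMILES string", smiles=smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidityError(f"unparseable or valence-violating SMILES: {smiles!r}",
                            smiles=smiles)
    try:
        Chem.Kekulize(mol, clearAromaticFlags=True)
    except Chem.KekulizeException as exc:
        raise ValidityError(f"cannot kekulize {smiles!r}", smiles=smiles) from exc
    nodes = [(a.GetSymbol(), a.GetFormalCharge()) for a in mol.GetAtoms()]
    edges = set()
    for b in mol.GetBonds():
        i, j = sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        order = int(b.GetBondTypeAsDouble())
        if order not in BOND_ORDERS:
            raise ValidityError(f"unsupported bond order in {smiles!r}", smiles=smiles)
        edges.add((i, j, order))
    return MolecularGraph(nodes, edges, terminated=True)


def _to_rdkit(graph: MolecularGraph) -> Chem.Mol:
    rw = Chem.RWMol()
    for element, charge in graph.nodes:
        atom = Chem.Atom(element)
        atom.SetFormalCharge(charge)
        rw.AddAtom(atom)
    for i, j, order in graph.edges:
        rw.AddBond(i, j, _RD_BOND[order])
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def to_canonical_smiles(graph: MolecularGraph) -> str:
    """Emit canonical (Daylight-style) SMILES; aromatic rings re-perceived."""
    if graph.n_nodes == 0:
        raise ValidityError("cannot emit SMILES for an empty graph")
    try:
        mol = _to_rdkit(graph)
    except Exception as exc:
        raise ValidityError(f"graph fails sanitization: {exc}") from exc
    return Chem.MolToSmiles(mol)


def is_valid(graph: MolecularGraph) -> bool:
    """True iff the graph is a non-empty, connected, sanitizable molecule."""
    if graph.n_nodes == 0 or not graph.is_connected():
        return False
    for idx in range(graph.n_nodes):
        if graph.free_valence(idx) < 0:
            return False
    try:
        to_canonical_smiles(graph)
    except ValidityError:
        return False
    return True


# ---------------------------------------------------------------------------
# Action application
# ---------------------------------------------------------------------------

def apply_action(graph: MolecularGraph, action: Action) -> MolecularGraph:
    """Return a new graph with the action applied; the input is untouched."""
    if graph.terminated:
        raise InvalidActionError("graph already terminated")
    new = graph.copy()
    if action.kind is ActionKind.TERMINATE:
        new.terminated = True
        return new
    if action.kind is ActionKind.ADD:
        if action.element is None:
            raise InvalidActionError("ADD requires an element")
        if action.charge not in CHARGES:
            raise InvalidActionError(f"charge {action.charge} outside {CHARGES}")
        if action.attach_to is None:
            if graph.n_nodes != 0:
                raise InvalidActionError("ADD with no attach node only on empty graph")
            new.nodes.append((action.element, action.charge))
            return new
        if graph.n_nodes == 0:
            raise InvalidActionError("cannot attach to a node of the empty graph")
        if not (0 <= action.attach_to < graph.n_nodes):
            raise InvalidActionError(f"attach index {action.attach_to} out of range")
        order = action.bond_order
        if order not in BOND_ORDERS:
            raise InvalidActionError(f"bond order {order} not in {BOND_ORDERS}")
        if graph.free_valence(action.attach_to) < order:
            raise InvalidActionError("valence exceeded on attach node")
        if valence_cap(action.element, action.charge) < order:
            raise InvalidActionError("valence exceeded on new node")
        new.nodes.append((action.element, action.charge))
        new.edges.add((action.attach_to, new.n_nodes - 1, order))
        return new
    if action.kind is ActionKind.CONNECT:
        i, j, order = action.i, action.j, action.bond_order
        if i is None or j is None or i == j:
            raise InvalidActionError("CONNECT needs two distinct indices")
        if not (0 <= i < graph.n_nodes and 0 <= j < graph.n_nodes):
            raise InvalidActionError("CONNECT index out of range")
        if order not in BOND_ORDERS:
            raise InvalidActionError(f"bond order {order} not in {BOND_ORDERS}")
        lo, hi = min(i, j), max(i, j)
        if any((lo, hi) == (a, b) for a, b, _ in graph.edges):
            raise InvalidActionError(f"edge ({lo},{hi}) already present")
        if graph.free_valence(i) < order or graph.free_valence(j) < order:
            raise InvalidActionError("valence exceeded on connect")
        new.edges.add((lo, hi, order))
        return new
    raise InvalidActionError(f"unknown action kind {action.kind}")


def replay(route: DecodingRoute) -> MolecularGraph:
    """Rebuild the final graph by applying the route's actions from scratch."""
    g = MolecularGraph()
    for _, action in route.steps:
        g = apply_action(g, action)
    return g


# ---------------------------------------------------------------------------
# Canonical deconstruction
# ---------------------------------------------------------------------------

def deconstruction_route(graph: MolecularGraph) -> DecodingRoute:
    """Canonical-rank-seeded BFS route whose replay reproduces the graph.

    Nodes are visited breadth-first starting from the atom with the lowest
    RDKit canonical rank, neighbor order broken by canonical rank.  Each
    visited node yields one ADD (bonded to its earliest-visited neighbor);
    any further bonds back into the visited set yield CONNECT actions in
    visit order; the route ends with TERMINATE.  Node indices in the route's
    graphs follow visit order, so the final graph is a relabeling of the
    input that canonicalizes to the same SMILES.
    """
    if not graph.terminated:
        raise ContractError("deconstruction requires a terminated graph")
    if graph.n_nodes == 0:
        raise ContractError("cannot deconstruct an empty graph")
    if not graph.is_connected():
        raise UnsupportedInputError("disconnected graphs are not supported")

    mol = _to_rdkit(graph)
    rank = list(Chem.CanonicalRankAtoms(mol))
    start = min(range(graph.n_nodes), key=lambda k: rank[k])

    order: list[int] = [start]
    pos = {start: 0}
    queue = deque([start])
    bond_of = {}
    adj: dict[int, list[int]] = {k: [] for k in range(graph.n_nodes)}
    for i, j, o in graph.edges:
        adj[i].append(j)
        adj[j].append(i)
        bond_of[(i, j)] = bond_of[(j, i)] = o
    while queue:
        v = queue.popleft()
        for w in sorted(adj[v], key=lambda k: rank[k]):
            if w not in pos:
                pos[w] = len(order)
                order.append(w)
                queue.append(w)

    steps: list[tuple[MolecularGraph, Action]] = []
    g = MolecularGraph()
    placed_edges: set[tuple[int, int]] = set()
    for new_idx, old in enumerate(order):
        element, charge = graph.nodes[old]
        if new_idx == 0:
            action = Action.add(None, element, charge, None)
        else:
            parents = [u for u in adj[old] if pos[u] < new_idx]
            attach_old = min(parents, key=lambda u: pos[u])
            action = Action.add(pos[attach_old], element, charge,
                                bond_of[(attach_old, old)])
            placed_edges.add((min(pos[attach_old], new_idx),
                              max(pos[attach_old], new_idx)))
        steps.append((g, action))
        g = apply_action(g, action)
        for u in sorted((u for u in adj[old] if pos[u] < new_idx),
                        key=lambda u: pos[u]):
            lo, hi = min(pos[u], new_idx), max(pos[u], new_idx)
            if (lo, hi) in placed_edges:
                continue
            action = Action.connect(lo, hi, bond_of[(u, old)])
            placed_edges.add((lo, hi))
            steps.append((g, action))
            g = apply_action(g, action)
    steps.append((g, Action.terminate()))
    g = apply_action(g, Action.terminate())
    return DecodingRoute(steps, g)


def graphs_match_chemically(a: MolecularGraph, b: MolecularGraph) -> bool:
    """Same molecule up to atom relabeling (canonical SMILES equality)."""
    return to_canonical_smiles(a) == to_canonical_smiles(b)


# ---------------------------------------------------------------------------
# JSON-lines route serialization (preprocessing blocks)
# ---------------------------------------------------------------------------
# One route per line: {"smiles": <canonical>, "actions": [<action>, ...]}
# where an action is ["add", attach|null, element, charge, order|null],
# ["connect", i, j, order] or ["terminate"].

def action_to_json(action: Action) -> list:
    if action.kind is ActionKind.TERMINATE:
        return ["terminate"]
    if action.kind is ActionKind.ADD:
        return ["add", action.attach_to, action.element, action.charge,
                action.bond_order]
    return ["connect", action.i, action.j, action.bond_order]


def action_from_json(blob: Iterable) -> Action:
    blob = list(blob)
    if blob[0] == "terminate":
        return Action.terminate()
    if blob[0] == "add":
        return Action.add(blob[1], blob[2], blob[3], blob[4])
    if blob[0] == "connect":
        return Action.connect(blob[1], blob[2], blob[3])
    raise ValidityError(f"unknown serialized action {blob[0]!r}")


def route_to_json(route: DecodingRoute) -> dict:
    return {"smiles": to_canonical_smiles(route.final),
            "actions": [action_to_json(a) for a in route.actions]}


def route_from_json(blob: dict) -> DecodingRoute:
    steps = []
    g = MolecularGraph()
    for raw in blob["actions"]:
        action = action_from_json(raw)
        steps.append((g, action))
        g = apply_action(g, action)
    return DecodingRoute(steps, g)
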