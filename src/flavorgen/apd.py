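"""Action probability distribution (APD) layout.

The model scores every graph-building action with one flat logit vector that
softmax-normalizes to a single distribution.  Blocks, in order:

* ``f_add``   — shape (max_nodes, elements, charges, bond orders): add a new
  atom bonded to an existing node slot.
* ``f_first`` — shape (elements, charges): place the first atom of an empty
  graph (no attachment, no bond order).
* ``f_conn``  — shape (max_nodes, bond orders): connect the most recently
  added node to an earlier node slot (ring closure).
* ``f_term``  — scalar: finish the graph.

Slots that do not exist in the current partial graph are masked before
sampling, so the emitted distribution is always over applicable actions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .graphs import BOND_ORDERS, CHARGES, Action, ActionKind, MolecularGraph

MASK_LOGIT = -1e30


@dataclass(frozen=True)
class APDLayout:
    elements: tuple[str, ...]
    max_nodes: int
    charges: tuple[int, ...] = CHARGES
    bond_orders: tuple[int, ...] = BOND_ORDERS

    def __post_init__(self) -> None:
        if not self.elements:
            raise ConfigError("element vocabulary must be non-empty")
        if self.max_nodes < 1:
            raise ConfigError("max_nodes must be >= 1")

    @property
    def n_add(self) -> int:
        return (self.max_nodes * len(self.elements) * len(self.charges)
                * len(self.bond_orders))

    @property
    def n_first(self) -> int:
        return len(self.elements) * len(self.charges)

    @property
    def n_conn(self) -> int:
        return self.max_nodes * len(self.bond_orders)

    @property
    def size(self) -> int:
        return self.n_add + self.n_first + self.n_conn + 1

    # -- index arithmetic ---------------------------------------------------

    def _add_index(self, slot: int, element: str, charge: int, order: int) -> int:
        e = self.elements.index(element)
        q = self.charges.index(charge)
        b = self.bond_orders.index(order)
        ne, nq, nb = len(self.elements), len(self.charges), len(self.bond_orders)
        return ((slot * ne + e) * nq + q) * nb + b

    def encode(self, action: Action, n_nodes: int) -> int:
        """Flat index of an action taken on a graph with ``n_nodes`` nodes."""
        if action.kind is ActionKind.TERMINATE:
            return self.size - 1
        if action.kind is ActionKind.ADD:
            if action.attach_to is None:
                e = self.elements.index(action.element)
                q = self.charges.index(action.charge)
                return self.n_add + e * len(self.charges) + q
            return self._add_index(action.attach_to, action.element,
                                   action.charge, action.bond_order)
        if action.kind is ActionKind.CONNECT:
            # The newer endpoint is always the last node; the slot encodes
            # the older endpoint.
            slot = min(action.i, action.j)
            b = self.bond_orders.index(action.bond_order)
            return self.n_add + self.n_first + slot * len(self.bond_orders) + b
        raise ConfigError(f"cannot encode action kind {action.kind}")

    def decode(self, index: int, n_nodes: int) -> Action:
        """Inverse of encode for a graph currently holding ``n_nodes`` nodes."""
        if index == self.size - 1:
            return Action.terminate()
        ne, nq, nb = len(self.elements), len(self.charges), len(self.bond_orders)
        if index < self.n_add:
            slot, rest = divmod(index, ne * nq * nb)
            e, rest = divmod(rest, nq * nb)
            q, b = divmod(rest, nb)
            return Action.add(slot, self.elements[e], self.charges[q],
                              self.bond_orders[b])
        index -= self.n_add
        if index < self.n_first:
            e, q = divmod(index, nq)
            return Action.add(None, self.elements[e], self.charges[q], None)
        index -= self.n_first
        slot, b = divmod(index, nb)
        return Action.connect(slot, n_nodes - 1, self.bond_orders[b])

    def mask(self, graph: MolecularGraph) -> np.ndarray:
        """Additive logit mask (0 where applicable, MASK_LOGIT elsewhere)."""
        n = graph.n_nodes
        ne, nq, nb = len(self.elements), len(self.charges), len(self.bond_orders)
        add = np.full((self.max_nodes, ne, nq, nb), MASK_LOGIT)
        if n < self.max_nodes:
            add[:n] = 0.0
        first = np.full((ne, nq), MASK_LOGIT if n > 0 else 0.0)
        conn = np.full((self.max_nodes, nb), MASK_LOGIT)
        if n >= 2:
            conn[:n - 1] = 0.0
        term = np.zeros(1)
        return np.concatenate([add.ravel(), first.ravel(), conn.ravel(), term])


@dataclass
class APD:
    """Masked, normalized action distribution for one partial graph."""

    probabilities: np.ndarray  # flat, layout order, sums to 1
    layout: APDLayout
    n_nodes: int

    @property
    def f_add(self) -> np.ndarray:
        lo = self.layout
        return self.probabilities[:lo.n_add].reshape(
            lo.max_nodes, len(lo.elements), len(lo.charges), len(lo.bond_orders))

    @property
    def f_first(self) -> np.ndarray:
        lo = self.layout
        return self.probabilities[lo.n_add:lo.n_add + lo.n_first].reshape(
            len(lo.elements), len(lo.charges))

    @property
    def f_conn(self) -> np.ndarray:
        lo = self.layout
        start = lo.n_add + lo.n_first
        return self.probabilities[start:start + lo.n_conn].reshape(
            lo.max_nodes, len(lo.bond_orders))

    @property
    def f_term(self) -> float:
        return float(self.probabilities[-1])

    def sample_index(self, rng: np.random.Generator) -> int:
        return int(rng.choice(self.probabilities.size, p=self.probabilities))
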