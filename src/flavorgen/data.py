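"""Flavor-molecule dataset: loading, curation, splitting and fixtures.

The loader consumes a local CSV snapshot with columns
``id,name,smiles,descriptors`` (descriptors ';'-separated sensory labels such
as "sweet" or "fruity").  Curation canonicalizes SMILES, drops unparseable
rows and merges duplicate molecules by unioning their descriptor sets.  The
fixture generator emits small organic molecules (C/N/O/S, 5-15 heavy atoms)
tagged with descriptors drawn from a skewed frequency table, emulating the
shape of a real flavor database so every downstream stage is testable
offline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import graphs
from .errors import ConfigError, FormatError
from .graphs import MolecularGraph, parse_smiles, to_canonical_smiles

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("id", "name", "smiles", "descriptors")

#: Descriptor vocabulary for fixtures, most common first ("sweet" dominates).
FIXTURE_DESCRIPTORS = (
    "sweet", "bitter", "fruity", "green", "floral", "woody", "fatty",
    "citrus", "spicy", "herbal", "nutty", "roasted", "earthy", "balsamic",
    "caramellic", "winey",
)


@dataclass
class FlavorRecord:
    """One molecule row: opaque id, display name, SMILES, sensory labels."""

    compound_id: str
    name: str
    smiles: str
    descriptors: set[str] = field(default_factory=set)


def load_records(path) -> list[FlavorRecord]:
    """Read a flavor CSV snapshot into records.

    Descriptor strings are lowercased, trimmed and deduplicated.  An empty
    file yields an empty list; a missing required column raises FormatError.
    """
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    for col in REQUIRED_COLUMNS:
        if col not in frame.columns:
            raise FormatError(f"missing required column {col!r}")
    records = []
    for row in frame.itertuples(index=False):
        raw = getattr(row, "descriptors") or ""
        descriptors = {d.strip().lower() for d in raw.split(";") if d.strip()}
        records.append(FlavorRecord(str(row.id), str(row.name), str(row.smiles),
                                    descriptors))
    return records


def save_records(records: list[FlavorRecord], path) -> None:
    frame = pd.DataFrame(
        {
            "id": [r.compound_id for r in records],
            "name": [r.name for r in records],
            "smiles": [r.smiles for r in records],
            "descriptors": [";".join(sorted(r.descriptors)) for r in records],
        }
    )
    frame.to_csv(path, index=False)


def curate(records: list[FlavorRecord]) -> list[FlavorRecord]:
    """Canonicalize SMILES, drop unparseable rows, merge duplicates.

    Duplicate molecules (same canonical SMILES) collapse onto the first
    occurrence with descriptor sets unioned.  Total function: bad rows are
    logged and dropped, never raised.
    """
    merged: dict[str, FlavorRecord] = {}
    dropped = 0
    for rec in records:
        try:
            canonical = to_canonical_smiles(parse_smiles(rec.smiles))
        except graphs.ValidityError:
            dropped += 1
            continue
        if canonical in merged:
            merged[canonical].descriptors |= rec.descriptors
        else:
            merged[canonical] = FlavorRecord(rec.compound_id, rec.name,
                                             canonical, set(rec.descriptors))
    if dropped:
        logger.info("curation dropped %d unparseable record(s)", dropped)
    return list(merged.values())


@dataclass(frozen=True)
class SplitSpec:
    """Train/test/validation fractions plus the shuffle seed."""

    train: float = 0.6
    test: float = 0.2
    validation: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.train, self.test, self.validation)
        if any(f < 0 for f in fracs):
            raise ConfigError("split fractions must be non-negative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ConfigError(f"split fractions must sum to 1, got {sum(fracs)}")


def split(records: list[FlavorRecord], spec: SplitSpec):
    """Seeded uniform shuffle into (train, test, validation).

    Sizes are round(n * fraction) for test and validation with the remainder
    assigned to train, so the partition is exhaustive and disjoint and a
    fixed seed reproduces membership exactly.
    """
    n = len(records)
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_test = round(n * spec.test)
    n_val = round(n * spec.validation)
    n_train = n - n_test - n_val
    train = [records[i] for i in perm[:n_train]]
    test = [records[i] for i in perm[n_train:n_train + n_test]]
    val = [records[i] for i in perm[n_train + n_test:]]
    return train, test, val


def descriptor_frequency(records: list[FlavorRecord]) -> list[tuple[str, int]]:
    """Per-descriptor record counts, sorted by count desc then name asc."""
    counts: dict[str, int] = {}
    for rec in records:
        for d in rec.descriptors:
            counts[d] = counts.get(d, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def descriptor_cooccurrence(records: list[FlavorRecord], top_k: int) -> pd.DataFrame:
    """Symmetric co-occurrence counts over the top-k descriptors.

    Entry (a, b) counts records tagged with both; the diagonal is each
    descriptor's frequency.  top_k beyond the vocabulary is clamped.
    """
    if top_k < 1:
        raise ConfigError("top_k must be >= 1")
    ranked = descriptor_frequency(records)
    if top_k > len(ranked):
        logger.warning("top_k=%d exceeds %d distinct descriptors; clamping",
                       top_k, len(ranked))
        top_k = len(ranked)
    names = [d for d, _ in ranked[:top_k]]
    index = {d: k for k, d in enumerate(names)}
    mat = np.zeros((top_k, top_k), dtype=int)
    for rec in records:
        tagged = sorted(index[d] for d in rec.descriptors if d in index)
        for a in tagged:
            for b in tagged:
                mat[a, b] += 1
    return pd.DataFrame(mat, index=names, columns=names)


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

_FIXTURE_ELEMENTS = ("C", "N", "O", "S")
# Organic-looking composition: carbon-dominated with scattered heteroatoms.
_ELEMENT_WEIGHTS = (0.72, 0.10, 0.15, 0.03)


def _random_graph(rng: np.random.Generator) -> MolecularGraph:
    """Random tree over C/N/O/S with occasional double bonds and one small
    ring closure, 5-15 heavy atoms, valence caps respected by construction."""
    n_atoms = int(rng.integers(5, 16))
    g = MolecularGraph()
    g = graphs.apply_action(g, graphs.Action.add(None, "C", 0, None))
    while g.n_nodes < n_atoms:
        open_sites = [k for k in range(g.n_nodes) if g.free_valence(k) >= 1]
        if not open_sites:
            break
        attach = int(rng.choice(open_sites))
        if g.nodes[attach][0] == "C":
            element = str(rng.choice(_FIXTURE_ELEMENTS, p=_ELEMENT_WEIGHTS))
        else:
            element = "C"  # keep heteroatoms isolated, as in real flavor sets
        order = 2 if (rng.random() < 0.12 and g.free_valence(attach) >= 2
                      and graphs.valence_cap(element, 0) >= 2) else 1
        g = graphs.apply_action(g, graphs.Action.add(attach, element, 0, order))
    if rng.random() < 0.35:  # close one ring of size >= 3 when geometry allows
        candidates = [
            (i, j)
            for i in range(g.n_nodes)
            for j in range(i + 1, g.n_nodes)
            if g.free_valence(i) >= 1 and g.free_valence(j) >= 1
            and not any((i, j) == (a, b) for a, b, _ in g.edges)
        ]
        if candidates:
            i, j = candidates[int(rng.integers(len(candidates)))]
            g = graphs.apply_action(g, graphs.Action.connect(i, j, 1))
    return graphs.apply_action(g, graphs.Action.terminate())


def _sample_descriptors(rng: np.random.Generator) -> set[str]:
    # Zipf-like weights so "sweet" dominates, matching a skewed label census.
    weights = np.array([1.0 / (k + 1) for k in range(len(FIXTURE_DESCRIPTORS))])
    weights /= weights.sum()
    count = int(rng.integers(1, 6))
    picks = rng.choice(len(FIXTURE_DESCRIPTORS), size=count, replace=True,
                       p=weights)
    return {FIXTURE_DESCRIPTORS[k] for k in picks}


def generate_fixtures(n: int, seed: int) -> list[FlavorRecord]:
    """Generate n unique, curated flavor-like records, deterministic in seed."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    records: list[FlavorRecord] = []
    while len(records) < n:
        g = _random_graph(rng)
        if not graphs.is_valid(g):
            continue
        smiles = to_canonical_smiles(g)
        if smiles in seen:
            continue
        seen.add(smiles)
        idx = len(records) + 1
        records.append(FlavorRecord(f"FIX{idx:05d}", f"fixture-{idx}", smiles,
                                    _sample_descriptors(rng)))
    return records
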