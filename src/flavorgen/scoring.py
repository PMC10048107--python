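"""Reward stack: synthetic accessibility, natural-product likeness, size.

Both fragment scores follow the published fragment-contribution methods: a
molecule is decomposed into circular atom environments (Morgan radius 2) and
each fragment looks up a tabulated contribution.

* Synthetic accessibility (SAScore): count-weighted mean fragment
  contribution minus a structural-complexity penalty (size, spiro and
  bridgehead atoms, macrocycles; the stereo term is zero here since
  stereochemistry is out of scope) plus a symmetry correction, affinely
  mapped onto [1, 10] where 1 = easiest to synthesize.
* Natural-product likeness (NPScore): sum of fragment contributions divided
  by heavy-atom count, with logarithmic compression beyond ±4 and a final
  clamp to [-5, 5]; positive values look natural-product-like, values near
  zero pseudo-natural.

Contribution tables are pluggable: a two-column text reader, loaders for the
published reference tables shipped with RDKit, and a builder that calibrates
a small table from a record set's own fragment frequencies (used by the test
fixtures).  Rewards map both scores onto [0, 1]; the final score is the
equal-weight mean of the SA, NP and target-size rewards with the exclusion
rules for invalid, unfinished and duplicate molecules.
"""

from __future__ import annotations

import gzip
import math
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import RDConfig, rdMolDescriptors

from .errors import ContractError, FormatError, ValidityError
from .graphs import MolecularGraph, _to_rdkit, is_valid, to_canonical_smiles
from .model import SampledMolecule

SA_DEFAULT_CONTRIBUTION = -4.0
NP_DEFAULT_CONTRIBUTION = 0.0


@dataclass
class FragmentScoreTable:
    """Circular-fragment (radius <= 2) identifier -> contribution mapping."""

    contributions: dict[int, float]
    default: float = 0.0

    def __post_init__(self) -> None:
        for key, value in self.contributions.items():
            if not math.isfinite(value):
                raise FormatError(f"non-finite contribution for fragment {key}")

    def get(self, fragment_id: int) -> float:
        return self.contributions.get(fragment_id, self.default)

    def __contains__(self, fragment_id: int) -> bool:
        return fragment_id in self.contributions


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def _open_maybe_gzip(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_table(path, default: float = 0.0) -> FragmentScoreTable:
    """Read a two-column (fragment-id, value) text table; gzip tolerated."""
    contributions: dict[int, float] = {}
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"line {lineno}: expected 2 columns")
            try:
                contributions[int(parts[0])] = float(parts[1])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
    return FragmentScoreTable(contributions, default)


def write_table(table: FragmentScoreTable, path) -> None:
    with open(path, "w") as fh:
        for key in sorted(table.contributions):
            fh.write(f"{key} {table.contributions[key]:.6f}\n")


def load_reference_sa_table() -> FragmentScoreTable:
    """Published SA fragment contributions shipped with RDKit."""
    path = Path(RDConfig.RDContribDir) / "SA_Score" / "fpscores.pkl.gz"
    data = pickle.load(gzip.open(path))
    contributions = {}
    for row in data:
        for fragment_id in row[1:]:
            contributions[fragment_id] = float(row[0])
    return FragmentScoreTable(contributions, SA_DEFAULT_CONTRIBUTION)


def load_reference_np_table() -> FragmentScoreTable:
    """Published natural-product fragment contributions shipped with RDKit."""
    path = Path(RDConfig.RDContribDir) / "NP_Score" / "publicnp.model.gz"
    data = pickle.load(gzip.open(path))
    return FragmentScoreTable({int(k): float(v) for k, v in data.items()},
                              NP_DEFAULT_CONTRIBUTION)


def _fragment_counts(mol: Chem.Mol) -> dict[int, int]:
    fp = rdMolDescriptors.GetMorganFingerprint(mol, 2)
    return dict(fp.GetNonzeroElements())


def fixture_tables(smiles_list: Iterable[str], clip: float = 3.0
                   ) -> tuple[FragmentScoreTable, FragmentScoreTable]:
    """Calibrate small (SA, NP) tables from a record set's fragments.

    Contribution = log of a fragment's count relative to the mean count, so
    common fragments score as easy/natural and rare ones as hard/unusual --
    the same frequency logic the published tables are calibrated with, at
    fixture scale.
    """
    counts: dict[int, int] = {}
    for smiles in smiles_list:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        for fragment_id, count in _fragment_counts(mol).items():
            counts[fragment_id] = counts.get(fragment_id, 0) + count
    if not counts:
        raise ContractError("no fragments found to calibrate tables")
    mean = sum(counts.values()) / len(counts)
    contributions = {
        k: float(np.clip(math.log(v / mean + 1e-9), -clip, clip))
        for k, v in counts.items()
    }
    sa = FragmentScoreTable(dict(contributions), SA_DEFAULT_CONTRIBUTION)
    np_table = FragmentScoreTable(dict(contributions), NP_DEFAULT_CONTRIBUTION)
    return sa, np_table


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def _require_valid(graph: MolecularGraph) -> Chem.Mol:
    if not is_valid(graph):
        raise ValidityError("scoring requires a valid molecular graph")
    return _to_rdkit(graph)


def sa_score(graph: MolecularGraph, table: FragmentScoreTable) -> float:
    """Synthetic accessibility in [1, 10]; 1 = easiest to synthesize."""
    mol = _require_valid(graph)
    counts = _fragment_counts(mol)
    total = sum(counts.values())
    fragment_term = sum(table.get(k) * v for k, v in counts.items()) / total

    n_atoms = mol.GetNumAtoms()
    ring_info = mol.GetRingInfo()
    n_spiro = rdMolDescriptors.CalcNumSpiroAtoms(mol)
    n_bridge = rdMolDescriptors.CalcNumBridgeheadAtoms(mol)
    n_macro = sum(1 for ring in ring_info.AtomRings() if len(ring) > 8)
    size_penalty = n_atoms ** 1.005 - n_atoms
    stereo_penalty = 0.0  # stereochemistry out of scope
    spiro_penalty = math.log10(n_spiro + 1)
    bridge_penalty = math.log10(n_bridge + 1)
    macro_penalty = math.log10(2) if n_macro > 0 else 0.0
    complexity = (size_penalty + stereo_penalty + spiro_penalty
                  + bridge_penalty + macro_penalty)

    symmetry = 0.0
    if n_atoms > len(counts):  # dense fingerprints => symmetric, easier
        symmetry = 0.5 * math.log(n_atoms / len(counts))

    raw = fragment_term - complexity + symmetry
    raw_min, raw_max = -4.0, 2.5
    score = 11.0 - (raw - raw_min + 1.0) / (raw_max - raw_min) * 9.0
    if score > 8.0:
        score = 8.0 + math.log(score + 1.0 - 9.0)
    return float(min(max(score, 1.0), 10.0))


def np_score(graph: MolecularGraph, table: FragmentScoreTable) -> float:
    """Natural-product likeness in [-5, 5]; higher = more natural-like."""
    mol = _require_valid(graph)
    counts = _fragment_counts(mol)
    score = sum(table.get(k) for k in counts) / mol.GetNumAtoms()
    if score > 4.0:
        score = 4.0 + math.log10(score - 4.0 + 1.0)
    elif score < -4.0:
        score = -4.0 - math.log10(-4.0 - score + 1.0)
    return float(min(max(score, -5.0), 5.0))


def size_reward(graph: MolecularGraph, max_nodes: int) -> int:
    """1 iff the node count lies in (0, max_nodes], else 0."""
    return int(0 < graph.n_nodes <= max_nodes)


def sa_reward(sa: float) -> float:
    """Affine decreasing map of SAScore onto [0, 1] (1 at SA=1, 0 at SA=10)."""
    if not 1.0 <= sa <= 10.0:
        raise ContractError(f"SAScore {sa} outside [1, 10]")
    return (10.0 - sa) / 9.0


def np_reward(np_value: float) -> float:
    """Affine increasing map of NPScore onto [0, 1] (0 at -5, 1 at +5)."""
    if not -5.0 <= np_value <= 5.0:
        raise ContractError(f"NPScore {np_value} outside [-5, 5]")
    return (np_value + 5.0) / 10.0


# ---------------------------------------------------------------------------
# Final score with exclusion rules
# ---------------------------------------------------------------------------

@dataclass
class ScoreBreakdown:
    smiles: Optional[str]
    sa_score: Optional[float] = None
    np_score: Optional[float] = None
    size_reward: int = 0
    sa_reward: float = 0.0
    np_reward: float = 0.0
    final_score: float = 0.0
    excluded: bool = False
    exclusion_reason: str = "none"  # invalid | duplicate | unfinished | none


def final_scores(sampled: Sequence[SampledMolecule],
                 sa_table: FragmentScoreTable,
                 np_table: FragmentScoreTable,
                 max_nodes: int) -> list[ScoreBreakdown]:
    """Equal-weight mean of the three rewards, with exclusions zeroed.

    A molecule is excluded (final score 0) if it is invalid, was not finished
    by the terminate action, or repeats an earlier molecule of the batch
    (same canonical SMILES; the first occurrence is kept).
    """
    seen: set[str] = set()
    out: list[ScoreBreakdown] = []
    for mol in sampled:
        if not mol.valid:
            out.append(ScoreBreakdown(None, excluded=True,
                                      exclusion_reason="invalid"))
            continue
        smiles = to_canonical_smiles(mol.graph)
        if not mol.properly_terminated:
            out.append(ScoreBreakdown(smiles, excluded=True,
                                      exclusion_reason="unfinished"))
            continue
        if smiles in seen:
            out.append(ScoreBreakdown(smiles, excluded=True,
                                      exclusion_reason="duplicate"))
            continue
        seen.add(smiles)
        sa = sa_score(mol.graph, sa_table)
        np_val = np_score(mol.graph, np_table)
        size = size_reward(mol.graph, max_nodes)
        r_sa = sa_reward(sa)
        r_np = np_reward(np_val)
        out.append(ScoreBreakdown(
            smiles, sa_score=sa, np_score=np_val, size_reward=size,
            sa_reward=r_sa, np_reward=r_np,
            final_score=(r_sa + r_np + size) / 3.0))
    return out


def optimality(breakdown: ScoreBreakdown) -> bool:
    """Optimal region: easily synthesizable (SA < 3) and natural (NP > 0)."""
    if breakdown.excluded:
        raise ContractError("optimality is undefined for excluded molecules")
    return breakdown.sa_score < 3.0 and breakdown.np_score > 0.0


def scores_to_frame(breakdowns: Sequence[ScoreBreakdown]):
    import pandas as pd

    return pd.DataFrame(
        {
            "smiles": [b.smiles for b in breakdowns],
            "sa": [b.sa_score for b in breakdowns],
            "np": [b.np_score for b in breakdowns],
            "size": [b.size_reward for b in breakdowns],
            "final": [b.final_score for b in breakdowns],
            "excluded_reason": [b.exclusion_reason for b in breakdowns],
        }
    )
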