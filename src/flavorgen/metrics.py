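"""Generated-set evaluation metrics.

For a sampled set: the fractions of valid (PV), unique-among-valid (PU),
properly terminated (PPT) and valid-among-terminated (PVPT) molecules, plus
the mean node count per graph (nu_av) and mean edges per node (eps_av) over
the valid molecules.  The uniformity-completeness Jensen-Shannon divergence
(UC-JSD) compares the per-molecule negative log-likelihood distributions of
the training, validation and sampled sets: a model that covers its data
uniformly drives the three distributions together and the divergence toward
zero, which is the generation metric used for snapshot selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError
from .model import SampledMolecule
from .graphs import to_canonical_smiles
from .scoring import ScoreBreakdown

UCJSD_BINS = 64
_EPS = 1e-12


@dataclass
class EvalReport:
    pv: float
    pu: float
    ppt: float
    pvpt: float
    nu_av: float
    eps_av: float
    uc_jsd: Optional[float] = None
    epoch: Optional[int] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "epoch": self.epoch, "PV": self.pv, "PVPT": self.pvpt,
                "PPT": self.ppt, "nu_av": self.nu_av, "eps_av": self.eps_av,
                "PU": self.pu, "UC-JSD": self.uc_jsd,
            }]
        )


def evaluate_set(sampled: Sequence[SampledMolecule],
                 epoch: Optional[int] = None) -> EvalReport:
    """Compute PV/PU/PPT/PVPT and the structural averages (UC-JSD unset)."""
    if not sampled:
        raise ContractError("cannot evaluate an empty sampled set")
    total = len(sampled)
    valid = [m for m in sampled if m.valid]
    terminated = [m for m in sampled if m.properly_terminated]
    valid_terminated = [m for m in sampled if m.valid and m.properly_terminated]
    pv = len(valid) / total
    ppt = len(terminated) / total
    pvpt = len(valid_terminated) / len(terminated) if terminated else 0.0
    if valid:
        unique = {to_canonical_smiles(m.graph) for m in valid}
        pu = len(unique) / len(valid)
        nu_av = float(np.mean([m.graph.n_nodes for m in valid]))
        eps_av = float(np.mean([
            2.0 * m.graph.n_edges / m.graph.n_nodes for m in valid]))
    else:
        pu, nu_av, eps_av = 0.0, 0.0, 0.0
    return EvalReport(pv=pv, pu=pu, ppt=ppt, pvpt=pvpt, nu_av=nu_av,
                      eps_av=eps_av, epoch=epoch)


def uc_jsd(nll_train: Sequence[float], nll_validation: Sequence[float],
           nll_sampled: Sequence[float], bins: int = UCJSD_BINS) -> float:
    """Jensen-Shannon divergence of three NLL histograms, in nats.

    The three lists are histogrammed on shared bins spanning their pooled
    range, each normalized (with an additive 1e-12 floor) to a probability
    vector; the result H(mean) - mean(H) lies in [0, ln 3].
    """
    lists = [np.asarray(x, dtype=float) for x in
             (nll_train, nll_validation, nll_sampled)]
    if any(x.size == 0 for x in lists):
        raise ContractError("uc_jsd requires three non-empty NLL lists")
    pooled = np.concatenate(lists)
    lo, hi = float(pooled.min()), float(pooled.max())
    if hi <= lo:
        hi = lo + 1.0  # all mass in one bin for degenerate inputs
    edges = np.linspace(lo, hi, bins + 1)
    dists = []
    for x in lists:
        hist, _ = np.histogram(x, bins=edges)
        p = hist.astype(float) + _EPS
        dists.append(p / p.sum())
    mean = np.mean(dists, axis=0)

    def entropy(p: np.ndarray) -> float:
        return float(-np.sum(p * np.log(p)))

    return entropy(mean) - float(np.mean([entropy(p) for p in dists]))


def score_range_table(breakdowns: Sequence[ScoreBreakdown],
                      metric: str) -> pd.DataFrame:
    """Percentage of non-excluded molecules per unit score bin.

    SA bins are [1,2) ... [9,10], NP bins [-5,-4) ... [4,5]; the top bin is
    closed so every scored molecule lands in exactly one bin and the
    percentages sum to 100.
    """
    if metric == "sa":
        edges = np.arange(1.0, 11.0)
        values = [b.sa_score for b in breakdowns if not b.excluded]
    elif metric == "np":
        edges = np.arange(-5.0, 6.0)
        values = [b.np_score for b in breakdowns if not b.excluded]
    else:
        raise ContractError(f"metric must be 'sa' or 'np', got {metric!r}")
    if not values:
        raise ContractError("score_range_table needs >= 1 non-excluded molecule")
    hist, _ = np.histogram(values, bins=edges)  # np.histogram closes top bin
    pct = 100.0 * hist / hist.sum()
    labels = [f"[{edges[k]:g},{edges[k + 1]:g})" for k in range(len(edges) - 2)]
    labels.append(f"[{edges[-2]:g},{edges[-1]:g}]")
    return pd.DataFrame({"bin": labels, "percent": pct})
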