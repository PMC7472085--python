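"""Decision-level multi-modal fusion by majority vote.

Each modality's classifier votes a quadrant per 1-s segment; the fused
decision is the modal class. Ties (inevitable with 2 or 4 voters) are broken
by the highest summed softmax probability among the tied classes, with a fixed
class order (HVHA < HVLA < LVHA < LVLA) as a final deterministic fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .labels import QUADRANTS

__all__ = ["VoteTable", "majority_vote", "fuse_report", "trial_vote"]

N_CLASSES = len(QUADRANTS)


@dataclass
class VoteTable:
    """Aligned per-segment class decisions for several modalities.

    ``votes`` maps modality → (n,) integer class codes; ``probs`` optionally
    maps modality → (n, 4) softmax outputs used by the confidence tie-break.
    All modalities must vote on the same segments in the same order
    (``provenance`` carries the shared alignment; if given, mismatched
    alignment is rejected).
    """

    votes: dict[str, np.ndarray]
    probs: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: pd.DataFrame | None = None
    targets: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.votes) < 1:
            raise ValueError("vote table needs at least one modality")
        lengths = {m: len(v) for m, v in self.votes.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"misaligned vote lengths: {lengths}")
        self.votes = {m: np.asarray(v, dtype=np.int64) for m, v in self.votes.items()}
        for m, p in self.probs.items():
            if m not in self.votes or len(p) != self.n_segments:
                raise ValueError(f"probabilities misaligned for modality {m!r}")

    @property
    def n_segments(self) -> int:
        return len(next(iter(self.votes.values())))

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(self.votes)

    def subset(self, modalities: tuple[str, ...]) -> "VoteTable":
        return VoteTable(
            {m: self.votes[m] for m in modalities},
            {m: self.probs[m] for m in modalities if m in self.probs},
            self.provenance,
            self.targets,
        )


def majority_vote(
    table: VoteTable, tie_rule: str = "confidence"
) -> tuple[np.ndarray, float | None]:
    """Fuse the table's votes; returns (fused codes, accuracy or None).

    ``tie_rule``: "confidence" breaks ties by summed softmax probability over
    the tied classes (falling back to class order when probabilities are
    absent or themselves tied); "order" always uses the fixed class order.
    """
    if len(table.votes) < 2:
        raise ValueError("fusion requires at least 2 modalities")
    if tie_rule not in ("confidence", "order"):
        raise ValueError(f"unknown tie rule {tie_rule!r}")
    mods = table.modalities
    vote_mat = np.stack([table.votes[m] for m in mods], axis=1)  # (n, k)
    n = len(vote_mat)
    tallies = np.zeros((n, N_CLASSES), dtype=np.int64)
    for j in range(vote_mat.shape[1]):
        np.add.at(tallies, (np.arange(n), vote_mat[:, j]), 1)
    top = tallies.max(axis=1, keepdims=True)
    tied = tallies == top  # candidate classes per segment
    if tie_rule == "confidence" and table.probs:
        conf = np.zeros((n, N_CLASSES))
        for m in mods:
            if m in table.probs:
                conf += table.probs[m]
        # rank by (is-candidate, confidence, reversed class order); argmax
        # takes the first maximum, so earlier classes win exact conf ties
        score = np.where(tied, conf, -np.inf)
        fused = score.argmax(axis=1)
    else:
        fused = tied.argmax(axis=1)  # first candidate in fixed class order
    acc = None
    if table.targets is not None:
        acc = float(np.mean(fused == np.asarray(table.targets)))
    return fused, acc


def trial_vote(
    predictions: np.ndarray,
    provenance: pd.DataFrame,
    probs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Trial-level decision: majority vote over a trial's segment predictions.

    An alternative granularity to per-segment fusion — all of one (subject,
    trial)'s segments vote for a single trial label, ties broken by summed
    probability then by class order. Returns one row per trial.
    """
    predictions = np.asarray(predictions, dtype=np.int64)
    if len(predictions) != len(provenance):
        raise ValueError("predictions misaligned with provenance")
    df = provenance[["subject", "trial"]].copy()
    df["pred"] = predictions
    rows = []
    for (subj, trial), grp in df.groupby(["subject", "trial"], sort=True):
        tally = np.bincount(grp["pred"], minlength=N_CLASSES)
        tied = tally == tally.max()
        if tied.sum() > 1 and probs is not None:
            conf = probs[grp.index.to_numpy()].sum(axis=0)
            label = int(np.where(tied, conf, -np.inf).argmax())
        else:
            label = int(tied.argmax())
        rows.append({"subject": subj, "trial": trial, "label": label,
                     "n_segments": len(grp)})
    return pd.DataFrame(rows)


def fuse_report(table: VoteTable, tie_rule: str = "confidence") -> pd.DataFrame:
    """Accuracy for every modality subset of size ≥ 2 (11 rows for 4 modalities).

    Single-modality accuracies are appended for reference when targets are
    known, mirroring how the per-modality and fused tables are read together.
    """
    if len(table.votes) < 2:
        raise ValueError("need at least 2 modalities")
    if table.targets is None:
        raise ValueError("fuse_report needs targets to compute accuracies")
    mods = table.modalities
    rows = []
    for size in range(2, len(mods) + 1):
        for combo in combinations(mods, size):
            fused, acc = majority_vote(table.subset(combo), tie_rule)
            rows.append({"modalities": " + ".join(combo), "size": size,
                         "accuracy_pct": 100.0 * acc})
    return pd.DataFrame(rows)
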