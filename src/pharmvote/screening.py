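"""Per-frame screening, vote accumulation and tie-aware ranking.

Each receptor conformation (frame) carries its own pharmacophore set.  A
molecule earns one vote per frame whose set it matches; the total vote
count over frames is its score.  Ties are frequent when few frames are
used, so the ranking keeps explicit tie blocks instead of jittering order —
the enrichment metrics handle tie blocks exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .library import MoleculeEntry
from .matcher import MatchOptions, match_molecule
from .pharmacophore import PharmacophoreSet


def select_frames(frames: list, n_select: int) -> list:
    """Evenly spaced (periodic) subset of an ordered trajectory, always
    including the last frame; deterministic floor-based arithmetic."""
    if n_select <= 0:
        raise ValueError("n_select must be positive")
    n = len(frames)
    if n_select > n:
        raise ValueError(f"cannot select {n_select} of {n} frames")
    idx = [(k + 1) * n // n_select - 1 for k in range(n_select)]
    return [frames[i] for i in idx]


@dataclass
class FrameMatchMatrix:
    """Boolean molecule x frame match matrix."""

    frames: list[int]
    molecules: list[str]
    matched: np.ndarray  # bool, shape (n_molecules, n_frames)

    def __post_init__(self):
        self.matched = np.asarray(self.matched, dtype=bool)
        if self.matched.shape != (len(self.molecules), len(self.frames)):
            raise ValueError("match matrix shape mismatch")

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.matched.astype(int),
            index=self.molecules,
            columns=[f"frame_{i}" for i in self.frames],
        )
        df.to_csv(path, sep="\t", index_label="molecule_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrameMatchMatrix":
        df = pd.read_csv(path, sep="\t", index_col="molecule_id")
        frames = [int(c.removeprefix("frame_")) for c in df.columns]
        return cls(frames=frames, molecules=list(df.index), matched=df.values.astype(bool))


@dataclass
class VoteTable:
    votes: dict[str, int]
    n_frames: int

    def __post_init__(self):
        for mol, v in self.votes.items():
            if not 0 <= v <= self.n_frames:
                raise ValueError(f"votes for {mol} outside [0, n_frames]")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("molecule_id\tvotes\n")
            for mol, v in self.votes.items():
                fh.write(f"{mol}\t{v}\n")


def screen_frame(
    library: list[MoleculeEntry],
    ps: PharmacophoreSet,
    opt: MatchOptions | None = None,
) -> set[str]:
    """Molecule ids matching at least one pharmacophore of this frame."""
    if not ps.pharmacophores:
        return set()
    opt = opt or MatchOptions()
    return {m.molecule_id for m in library if match_molecule(m, ps, opt)}


def screen_library(
    library: list[MoleculeEntry],
    pharm_sets: list[PharmacophoreSet],
    opt: MatchOptions | None = None,
) -> FrameMatchMatrix:
    """Screen every frame; frames with empty sets contribute all-zero columns
    but still count toward n_frames."""
    opt = opt or MatchOptions()
    mol_ids = [m.molecule_id for m in library]
    matched = np.zeros((len(library), len(pharm_sets)), dtype=bool)
    for j, ps in enumerate(pharm_sets):
        hits = screen_frame(library, ps, opt)
        for i, mid in enumerate(mol_ids):
            matched[i, j] = mid in hits
    return FrameMatchMatrix(
        frames=[ps.frame_index for ps in pharm_sets], molecules=mol_ids, matched=matched
    )


def accumulate_votes(matches: FrameMatchMatrix) -> VoteTable:
    row_sums = matches.matched.sum(axis=1)
    return VoteTable(
        votes={m: int(v) for m, v in zip(matches.molecules, row_sums)},
        n_frames=len(matches.frames),
    )


@dataclass
class RankedList:
    """Descending-vote ranking with explicit tie blocks.

    ``blocks[b]`` is the list of molecule ids sharing the b-th highest vote
    count, in stable input order.  ``ranks`` maps each id to its 1-based
    rank counted to the top of its block.
    """

    blocks: list[list[str]]
    block_votes: list[int]
    ranks: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.ranks:
            pos = 1
            for block in self.blocks:
                for mid in block:
                    self.ranks[mid] = pos
                pos += len(block)


def rank_molecules(votes: VoteTable) -> RankedList:
    """Rank by votes descending; equal-vote molecules share one tie block."""
    by_votes: dict[int, list[str]] = {}
    for mid, v in votes.votes.items():
        by_votes.setdefault(v, []).append(mid)
    blocks, block_votes = [], []
    for v in sorted(by_votes, reverse=True):
        blocks.append(by_votes[v])
        block_votes.append(v)
    return RankedList(blocks=blocks, block_votes=block_votes)
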