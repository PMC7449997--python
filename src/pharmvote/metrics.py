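"""Enrichment factors, enrichment plots and bootstrap-over-frames errors.

The enrichment factor at a screened fraction x is

    EF_x = (Hits^x% / N^x%) * (N^100% / Hits^100%)

i.e. the ligand concentration in the top x% of the ranking relative to the
whole library; EF > 1 means enrichment.  The enrichment plot (EP) traces
the percentage of ligands recovered against the percentage of the ranked
library screened.

Rankings by vote tie heavily at small frame counts, so both statistics are
tie-aware: when the top-N cutoff falls inside a tie block, the hit count is
the *expectation* under uniform random ordering within the block
(fractional hits).  This is deterministic, reproducible and unbiased —
a single all-tied block gives EF_x = 1 exactly at every x.

Uncertainty from the finite frame sample is estimated by bootstrap: frames
(columns of the match matrix) are resampled with replacement, votes and
the EP recomputed per replicate, and the pointwise mean and standard
deviation reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .screening import FrameMatchMatrix, RankedList, VoteTable, rank_molecules

DEFAULT_FRACTIONS = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0)
DEFAULT_N_BOOT = 100


class UndefinedEnrichmentError(ValueError):
    """No ligands in the library: enrichment is undefined."""


@dataclass
class LabeledRanking:
    """Ranked tie blocks plus ligand/decoy labels."""

    blocks: list[list[str]]
    labels: dict[str, str]  # molecule_id -> "ligand" | "decoy"

    n_total: int = field(init=False)
    hits_total: int = field(init=False)

    def __post_init__(self):
        ids = [m for b in self.blocks for m in b]
        missing = [m for m in ids if m not in self.labels]
        if missing:
            raise ValueError(f"unlabeled molecules in ranking: {missing[:5]}")
        self.n_total = len(ids)
        self.hits_total = sum(1 for m in ids if self.labels[m] == "ligand")

    @classmethod
    def from_ranked(cls, ranked: RankedList, labels: dict[str, str]) -> "LabeledRanking":
        return cls(blocks=ranked.blocks, labels=labels)


@dataclass
class EnrichmentCurve:
    fractions: np.ndarray  # % screened, ascending in (0, 100]
    ligands_found: np.ndarray  # % of ligands recovered
    std: np.ndarray | None = None

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.ligands_found = np.asarray(self.ligands_found, dtype=float)
        if self.std is not None:
            self.std = np.asarray(self.std, dtype=float)


def _top_n(x: float, n_total: int) -> int:
    """Compounds inspected at fraction x%: round-half-up with a floor of 1."""
    return max(1, int(np.floor(x / 100.0 * n_total + 0.5)))


def _expected_hits(r: LabeledRanking, n_top: int) -> float:
    """Expected ligand count in the top n_top, fractional across a straddled
    tie block (uniform random within-block order)."""
    seen = 0
    hits = 0.0
    for block in r.blocks:
        if seen >= n_top:
            break
        block_hits = sum(1 for m in block if r.labels[m] == "ligand")
        take = min(len(block), n_top - seen)
        if take == len(block):
            hits += block_hits
        else:
            hits += block_hits * take / len(block)
        seen += take
    return hits


def enrichment_factor(r: LabeledRanking, x: float) -> float:
    """Tie-aware EF at screened fraction x (percent)."""
    if not 0 < x <= 100:
        raise ValueError("x must be in (0, 100]")
    if r.hits_total < 1:
        raise UndefinedEnrichmentError("no ligands in the library")
    n_top = _top_n(x, r.n_total)
    hits = _expected_hits(r, n_top)
    return (hits / n_top) * (r.n_total / r.hits_total)


def enrichment_plot(
    r: LabeledRanking, fractions=DEFAULT_FRACTIONS
) -> EnrichmentCurve:
    """Percent of ligands found at each screened fraction (tie-aware)."""
    if r.hits_total < 1:
        raise UndefinedEnrichmentError("no ligands in the library")
    fr = np.asarray(sorted(fractions), dtype=float)
    found = np.array(
        [100.0 * _expected_hits(r, _top_n(x, r.n_total)) / r.hits_total for x in fr]
    )
    return EnrichmentCurve(fractions=fr, ligands_found=found)


def ef_table(r: LabeledRanking, fractions=DEFAULT_FRACTIONS) -> dict[float, float]:
    return {float(x): enrichment_factor(r, x) for x in fractions}


def bootstrap_enrichment(
    matches: FrameMatchMatrix,
    labels: dict[str, str],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    fractions=DEFAULT_FRACTIONS,
) -> tuple[EnrichmentCurve, EnrichmentCurve]:
    """Resample frames with replacement, recompute votes -> ranking -> EP per
    replicate; return (mean curve, std curve) pointwise over replicates."""
    if len(matches.frames) < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    n_frames = len(matches.frames)
    fr = np.asarray(sorted(fractions), dtype=float)
    curves = np.empty((n_boot, len(fr)))
    for b in range(n_boot):
        cols = rng.integers(0, n_frames, size=n_frames)
        row_sums = matches.matched[:, cols].sum(axis=1)
        votes = VoteTable(
            votes={m: int(v) for m, v in zip(matches.molecules, row_sums)},
            n_frames=n_frames,
        )
        r = LabeledRanking.from_ranked(rank_molecules(votes), labels)
        curves[b] = enrichment_plot(r, fr).ligands_found
    return (
        EnrichmentCurve(fr, curves.mean(axis=0), std=curves.std(axis=0)),
        EnrichmentCurve(fr, curves.std(axis=0)),
    )


def plot_enrichment(
    curves: dict[str, EnrichmentCurve], path=None, log_x: bool = True
):
    """Optional matplotlib rendering of EP curves (percentage axes, log x)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, c in curves.items():
        ax.plot(c.fractions, c.ligands_found, label=name)
        if c.std is not None:
            ax.fill_between(
                c.fractions,
                c.ligands_found - c.std,
                c.ligands_found + c.std,
                alpha=0.25,
            )
    if log_x:
        ax.set_xscale("log")
    ax.set_xlabel("% of library screened")
    ax.set_ylabel("% of ligands found")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
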