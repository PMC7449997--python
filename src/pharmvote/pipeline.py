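"""Full-protocol orchestration from a single config.

Stages per frame: affinity maps -> specificity filter -> hotspots ->
features -> pharmacophores -> screening; then votes -> ranking -> EF/EP ->
bootstrap.  Every stage persists its output under the run directory with a
manifest of content hashes, so any stage can be inspected, reloaded or
(with resume) skipped when its inputs are unchanged.  Frames are
independent of one another — any subset can be recomputed in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import ActiveSpace, HotspotConfig, features_for_frame
from .grids import GridMap, combine_acceptor_maps, read_autogrid_map
from .library import read_labels, read_library
from .matcher import MatchOptions
from .metrics import (
    DEFAULT_FRACTIONS,
    LabeledRanking,
    bootstrap_enrichment,
    ef_table,
    enrichment_plot,
)
from .pharmacophore import PharmacophoreSet, enumerate_pharmacophores, volume_exclusion
from .receptor import ReceptorConformation, read_pdb
from .screening import (
    FrameMatchMatrix,
    accumulate_votes,
    rank_molecules,
    screen_library,
    select_frames,
)
from .specificity import FilterPolicy, apply_specificity_filter, specificity_report

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str, frame: int | None = None):
        where = f"stage {stage}" + (f", frame {frame}" if frame is not None else "")
        super().__init__(f"{where}: {detail}")
        self.stage = stage
        self.frame = frame


class NoSignalError(PipelineError):
    """No pharmacophore could be built from any frame."""

    def __init__(self):
        super().__init__("pharmacophores", "empty pharmacophore set across all frames")


@dataclass
class RunConfig:
    frames_dir: str | Path
    library: str | Path
    labels: str | Path
    output_dir: str | Path
    maps_dir: str | Path | None = None  # None -> internal simplified calculator
    active_spaces: list[dict] = field(default_factory=list)  # {center, radius}
    hotspot: HotspotConfig = field(default_factory=HotspotConfig)
    policy: FilterPolicy = field(default_factory=FilterPolicy)
    match: MatchOptions = field(default_factory=MatchOptions)
    n_frames_select: int | None = None
    fractions: tuple = DEFAULT_FRACTIONS
    n_boot: int = 100
    seed: int = 0
    box_side: float = 12.5
    spacing: float = 0.25
    resume: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        kwargs = dict(doc)
        if "hotspot" in kwargs:
            kwargs["hotspot"] = HotspotConfig(**kwargs["hotspot"])
        if "policy" in kwargs:
            kwargs["policy"] = FilterPolicy(kurtosis_max=kwargs["policy"])
        if "match" in kwargs:
            kwargs["match"] = MatchOptions(**kwargs["match"])
        if "fractions" in kwargs:
            kwargs["fractions"] = tuple(kwargs["fractions"])
        return cls(**kwargs)

    def spaces(self) -> list[ActiveSpace]:
        if not self.active_spaces:
            raise ValueError("config must define at least one active space")
        return [
            ActiveSpace(
                id=s.get("id", f"space_{i}"),
                center=np.asarray(s["center"], dtype=float),
                radius=float(s.get("radius", 5.0)),
            )
            for i, s in enumerate(self.active_spaces)
        ]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    """Per-stage record of output files and their content hashes."""

    def __init__(self, path: Path):
        self.path = path
        self.data: dict = {}
        if path.exists():
            self.data = json.loads(path.read_text())

    def record(self, stage: str, files: list[Path], inputs_key: str = "") -> None:
        self.data[stage] = {
            "inputs": inputs_key,
            "files": {str(f): _sha256(f) for f in files},
        }
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))

    def is_current(self, stage: str, inputs_key: str = "") -> bool:
        rec = self.data.get(stage)
        if not rec or rec.get("inputs") != inputs_key:
            return False
        return all(
            Path(f).exists() and _sha256(Path(f)) == h for f, h in rec["files"].items()
        )


def load_frames(cfg: RunConfig) -> list[ReceptorConformation]:
    paths = sorted(Path(cfg.frames_dir).glob("*.pdb"))
    if not paths:
        raise PipelineError("frames", f"no PDB files under {cfg.frames_dir}")
    frames = [read_pdb(p, frame_index=i) for i, p in enumerate(paths)]
    if cfg.n_frames_select:
        frames = select_frames(frames, cfg.n_frames_select)
    return frames


def load_maps_for_frame(
    cfg: RunConfig, frame: ReceptorConformation, space: ActiveSpace
) -> list[GridMap]:
    """Read this frame's per-atom-type maps, or compute them internally."""
    if cfg.maps_dir is not None:
        fdir = Path(cfg.maps_dir) / f"frame_{frame.frame_index:04d}"
        paths = sorted(fdir.glob("*.map"))
        if not paths:
            raise PipelineError("grids", f"no .map files under {fdir}", frame.frame_index)
        maps = []
        for p in paths:
            g = read_autogrid_map(p)
            # trust the filename over the optional header tag
            g.atom_type = p.stem
            maps.append(g)
        return maps
    from .grids import simplified_affinity_map

    probes = ("donor", "acceptor_O", "acceptor_N", "acceptor_S",
              "hydrophobic", "aromatic", "charged")
    return [
        simplified_affinity_map(
            frame, probe, space.center, box_side=cfg.box_side, spacing=cfg.spacing
        )
        for probe in probes
    ]


def combine_acceptors(maps: list[GridMap]) -> list[GridMap]:
    """Replace the O/N/S acceptor flavors with one combined acceptor map."""
    acc = [m for m in maps if m.atom_type in ("acceptor_O", "acceptor_N", "acceptor_S")]
    rest = [m for m in maps if m.atom_type not in
            ("acceptor_O", "acceptor_N", "acceptor_S")]
    if acc:
        rest.append(combine_acceptor_maps(acc))
    return rest


def build_pharmacophores_for_frame(
    frame: ReceptorConformation,
    maps_by_space: dict[str, list[GridMap]],
    spaces: list[ActiveSpace],
    cfg: RunConfig,
) -> tuple[PharmacophoreSet, list[dict]]:
    """Filter each active space's maps, extract its features and enumerate
    triples; triples never mix features across active spaces."""
    exclusions = volume_exclusion(frame)
    pharms = []
    report: list[dict] = []
    for space in spaces:
        maps = combine_acceptors(maps_by_space[space.id])
        rows = specificity_report(maps, cfg.policy)
        for r in rows:
            r["active_space"] = space.id
        report.extend(rows)
        retained = apply_specificity_filter(maps, cfg.policy)
        feats = features_for_frame(
            retained, frame, space, cfg.hotspot, frame=frame.frame_index
        )
        pharms.extend(
            enumerate_pharmacophores(
                feats, exclusions, space, frame.frame_index,
                coexistence_min_dist=cfg.hotspot.coexistence_min_dist,
            )
        )
    return PharmacophoreSet(frame_index=frame.frame_index, pharmacophores=pharms), report


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the whole protocol; returns a summary dict and persists every
    stage under cfg.output_dir."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(out / "manifest.json")
    spaces = cfg.spaces()

    frames = load_frames(cfg)
    logger.info("loaded %d frames", len(frames))

    library = read_library(cfg.library)
    labels = read_labels(cfg.labels)

    # per-frame pharmacophore sets
    pharm_sets: list[PharmacophoreSet] = []
    filter_rows: list[dict] = []
    for fr in frames:
        try:
            if cfg.maps_dir is not None:
                shared = load_maps_for_frame(cfg, fr, spaces[0])
                maps_by_space = {s.id: shared for s in spaces}
            else:
                maps_by_space = {
                    s.id: load_maps_for_frame(cfg, fr, s) for s in spaces
                }
            ps, rows = build_pharmacophores_for_frame(fr, maps_by_space, spaces, cfg)
        except PipelineError:
            raise
        except Exception as exc:  # annotate with stage/frame context
            raise PipelineError("pharmacophores", str(exc), fr.frame_index) from exc
        for r in rows:
            r["frame"] = fr.frame_index
        filter_rows.extend(rows)
        pharm_sets.append(ps)
        logger.info("frame %d: %d pharmacophores", fr.frame_index, len(ps))
    pd.DataFrame(filter_rows).to_csv(out / "specificity.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"frame": ps.frame_index, "n_pharmacophores": len(ps)} for ps in pharm_sets]
    ).to_csv(out / "pharmacophore_counts.tsv", sep="\t", index=False)
    if not any(len(ps) for ps in pharm_sets):
        raise NoSignalError()

    # screening
    matrix_path = out / "match_matrix.tsv"
    screen_key = f"n_frames={len(frames)};n_mols={len(library)};x={cfg.hotspot.x_percent}"
    if cfg.resume and manifest.is_current("screen", screen_key):
        matches = FrameMatchMatrix.from_tsv(matrix_path)
        logger.info("screen stage reused from %s", matrix_path)
    else:
        matches = screen_library(library, pharm_sets, cfg.match)
        matches.to_tsv(matrix_path)
        manifest.record("screen", [matrix_path], screen_key)

    votes = accumulate_votes(matches)
    votes.to_tsv(out / "votes.tsv")
    ranked = rank_molecules(votes)
    labeled = LabeledRanking.from_ranked(ranked, labels)

    efs = ef_table(labeled, cfg.fractions)
    ep = enrichment_plot(labeled, cfg.fractions)
    mean_ep, std_ep = bootstrap_enrichment(
        matches, labels, n_boot=cfg.n_boot, seed=cfg.seed, fractions=cfg.fractions
    )
    pd.DataFrame(
        {
            "fraction_percent": ep.fractions,
            "EF": [efs[float(x)] for x in ep.fractions],
            "ligands_found_percent": ep.ligands_found,
            "bootstrap_mean": mean_ep.ligands_found,
            "bootstrap_std": mean_ep.std,
        }
    ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    manifest.record(
        "enrich", [out / "votes.tsv", out / "enrichment.tsv"], screen_key
    )
    return {
        "n_frames": len(frames),
        "n_molecules": len(library),
        "n_pharmacophores": int(sum(len(ps) for ps in pharm_sets)),
        "votes": votes,
        "ef": efs,
        "ep": ep,
        "bootstrap_mean": mean_ep,
        "bootstrap_std": std_ep,
        "match_matrix": matches,
        "output_dir": str(out),
    }
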