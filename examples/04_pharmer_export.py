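"""Export pharmacophores as Pharmer-compatible JSON queries.

The in-package matcher replaces Pharmer, but the JSON export lets the
original external tool be used as an alternative screening backend.
"""

from pathlib import Path

from pharmvote import SyntheticScenario, export_pharmer_json, read_pharmer_json
from pharmvote.pipeline import RunConfig, build_pharmacophores_for_frame
from pharmvote.synthetic import generate_grid_maps, generate_receptor_ensemble

sc = SyntheticScenario(seed=1)
space = sc.active_spaces()[0]
cfg = RunConfig(frames_dir="", library="", labels="", output_dir="",
                active_spaces=[{"center": [0.0, 0.0, 0.0]}])
frame = generate_receptor_ensemble(sc)[0]
ps, _ = build_pharmacophores_for_frame(
    frame, {space.id: generate_grid_maps(sc, 0)}, [space], cfg
)

out = Path("scratch/pharmer")
out.mkdir(parents=True, exist_ok=True)
path = out / "pharm_00000.json"
export_pharmer_json(ps.pharmacophores[0], path)
feats, exclusions = read_pharmer_json(path)
print(f"wrote {path}")
print(f"feature points : {[(f['name'], f['center'].round(2).tolist()) for f in feats]}")
print(f"exclusion spheres: {len(exclusions)} "
      f"(0.5 Å backbone atoms, 1.5 Å side-chain centers)")
print()
print("Each query holds 3 typed points with their matching radii plus the")
print("frame's full volume-exclusion list, in the point dialect Pharmer reads.")
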