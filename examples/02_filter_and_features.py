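"""From affinity maps to pharmacophoric features for one receptor frame.

Shows the kurtosis-based specificity filter in action (planted maps are
retained, flat/noise maps discarded) and the hotspot features it yields.
"""

import pandas as pd

from pharmvote import (
    SyntheticScenario,
    apply_specificity_filter,
    generate_grid_maps,
    generate_receptor_ensemble,
)
from pharmvote.features import features_for_frame
from pharmvote.specificity import specificity_report

sc = SyntheticScenario(seed=1)
frame = generate_receptor_ensemble(sc)[0]
maps = generate_grid_maps(sc, 0)

print("Specificity filter (Pearson kurtosis of the negative-energy histogram):")
print(pd.DataFrame(specificity_report(maps)).to_string(index=False))

retained = apply_specificity_filter(maps)
space = sc.active_spaces()[0]
feats = features_for_frame(retained, frame, space, frame=0)
print("\nFeatures inside the 5 Å active space:")
for f in feats:
    print(f"  {f.ftype:12s} center={f.center.round(2).tolist()}  rgyr={f.rgyr:.2f} Å")
print()
print("Low kurtosis = compact favorable region = specific site (retained).")
print("The noise map's half-normal histogram scores ~3.9 > 3 and is discarded;")
print("baseline maps have no negative cells and are discarded as empty.")
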