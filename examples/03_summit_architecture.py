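"""Where do peak summits sit relative to the start sites they regulate?

Signed summit-to-TSS offsets (downstream positive in transcription
direction) recover the planted +240 bp preference; promoters with a single
TSS in ±2 kb are clustered into upstream-only / downstream-only / both.
"""

import numpy as np

from promoter_architect import (
    cluster_promoters,
    positional_profile,
    select_single_tss_promoters,
    summit_offsets,
)
from promoter_architect.binding_architecture import build_architectures, cluster_fractions
from promoter_architect.synthetic_data import SimConfig, generate

bundle = generate(SimConfig(seed=11))
peaks = bundle.peaks["ZFX"]

offs = np.array([o for _, o in summit_offsets(peaks, bundle.tss)])
print(f"{len(offs)} summit-TSS pairs; median offset {np.median(offs):+.0f} bp")

profile = positional_profile(peaks, bundle.tss)
lo, hi = profile.modal_bin(smooth=5)
print(f"modal summit bin: [{lo:+d}, {hi:+d}) bp")
# The mode sits at +240 bp: the factor binds between the transcription
# start site and the first downstream nucleosome, not upstream like most
# sequence-specific factors.

single = select_single_tss_promoters(bundle.tss)
archs = build_architectures(peaks, single)
fractions = cluster_fractions(cluster_promoters(archs, method="rule"))
print("promoter architecture classes:",
      {k: round(v, 3) for k, v in fractions.items()})
# Downstream-only dominates; under 10% of bound single-TSS promoters carry
# the peak only upstream, and a small class has peaks on both sides.
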