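"""Generate a synthetic multi-batch dataset and quantify its batch effect.

The generator plants known per-batch location/scale distortions; the kNN
batch probe then measures how separable the batches are in the raw feature
space. nBE, ARI and AMI near 1 mean the probe identifies every sample's
batch — a strong batch effect; near 0 means batches are indistinguishable.
"""

from debatch import (BatchProbe, SyntheticConfig, evaluate_representation,
                     generate_synthetic)

for shift in (0.0, 0.3, 1.0):
    ds, truth = generate_synthetic(SyntheticConfig(batch_shift_sd=shift,
                                                   seed=0))
    rep = evaluate_representation(ds.values, ds, probe=BatchProbe(k=20))
    print(f"batch_shift_sd={shift:3.1f}  nBE={rep.nBE:.3f}  "
          f"ARI={rep.ARI:.3f}  AMI={rep.AMI:.3f}  "
          f"aPCC={rep.aPCC:.3f}  nMED={rep.nMED:.3f}")

print("\nRows: no batch effect -> mixing scores near 0; as the per-feature "
      "shift SD grows past the noise SD (0.5), the probe pins every "
      "sample's batch and the scores saturate at 1. aPCC/nMED track how "
      "tight the pooled-QC replicates stay.")
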