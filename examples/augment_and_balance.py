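"""Class balancing by label-preserving augmentation.

Builds an imbalanced labelled corpus (fewer clean than noisy segments),
applies the mirror + amplitude-modulation policy, and shows the resulting
class counts: every minority original contributes 3 variants (two mirrors,
one modulated), so n originals become exactly 4n, while the majority class
is augmented for a random subset until the counts nearly match.
"""

from respiqual import AugmentationPolicy, balance_augment, generate_dataset, uniform_protocol

spec = uniform_protocol("Sp", total_s=330.0, rate_range=(10, 16))
ds = generate_dataset(12, spec, {"noise-burst": 0.3, "amplitude-dropout": 0.3},
                      seed=4, seg_len_s=30.0)
print("before augmentation:", ds.class_counts())

policy = AugmentationPolicy(methods=("mirror", "modulate"), seed=0)
aug = balance_augment(ds, policy)
counts = aug.class_counts()
print("after augmentation: ", counts)
print(f"class difference {abs(counts['clean'] - counts['noisy'])} "
      f"<= {policy.variants_per_original} variants per original")
by_prov = {}
for seg in aug.segments:
    by_prov[seg.provenance] = by_prov.get(seg.provenance, 0) + 1
print("provenance mix:", by_prov)
# Augmented segments keep their source's label and breathing type; the
# provenance tag records which method produced each variant.
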