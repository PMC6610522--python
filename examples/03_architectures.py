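"""Build the three network families and audit their parameter counts.

Dilation widens receptive fields for free: a 3x3 filter at dilation k spans
k*(3-1)+1 pixels per side with the same nine weights.
"""
from wmhseg import ArchitectureSpec, build_model, count_parameters, receptive_field
from wmhseg.models import summarize

for family, ch in [("unet", 1), ("unet", 2), ("saliency_unet", 1),
                   ("dilated_saliency_unet", 1)]:
    model = build_model(ArchitectureSpec(family=family, in_channels=ch))
    print(f"{family:<24} ({ch} ch/branch): {count_parameters(model):>10,} parameters")

print()
for k in (1, 2, 3):
    print(f"3x3 filter, dilation {k}: {receptive_field(3, k)}x{receptive_field(3, k)} receptive field")

print()
print(summarize(build_model(ArchitectureSpec(family="dilated_saliency_unet", base_width=8))))
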