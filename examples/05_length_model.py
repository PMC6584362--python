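"""The closed-form length model and the contribution decomposition.

Evaluates L = sqrt(N sigma a / pi) (sqrt(s) + 1/sqrt(s)) at the two
species' 54 h APF parameters, then transforms the D. melanogaster
parameters with coefficient subsets to rank what drives the length
divergence: cell area (k_a) and tissue anisotropy (k_sigma) together are
essentially sufficient, while cell number (k_N) and shape (k_s)
contribute nothing.
"""

from ovimorph import (
    MELANOGASTER_54H,
    PUBLISHED_COEFFICIENTS,
    SUZUKII_54H,
    contribution_table,
    model_length,
)

l_mel = model_length(MELANOGASTER_54H)
l_suz = model_length(SUZUKII_54H)
print(f"model length, D. melanogaster 54 h APF: {l_mel:6.1f} um")
print(f"model length, D. suzukii      54 h APF: {l_suz:6.1f} um")
print(f"fold change: {l_suz / l_mel:.2f}\n")

table = contribution_table(MELANOGASTER_54H, PUBLISHED_COEFFICIENTS,
                           reference_length=l_suz)
print("melanogaster parameters transformed by coefficient subset:")
for _, row in table.iterrows():
    print(f"  {row['label']:>12}: {row.length_um:6.1f} um "
          f"({row.percent_of_reference:5.1f}% of the suzukii estimate)")
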