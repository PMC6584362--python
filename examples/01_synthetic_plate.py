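"""Generate a synthetic ovipositor plate and measure it back.

Builds a 45 x 29 tessellation at the D. melanogaster 54 h APF conditions
(mean apical area 11.68 um^2, shape ratio 1.57, ~52% of cells PD-aligned)
and runs the full morphometric summary: the recovered numbers should match
the generation parameters, which is the package's core self-check.
"""

from ovimorph import MEL_54H_PLATE, generate_hex_plate, summarize_plate

plate = generate_hex_plate(MEL_54H_PLATE)
summary = summarize_plate(plate)

print(f"cells segmented:        {plate.n_cells}")
print(f"corrected total N:      {summary.n_total:.0f}")
print(f"mean cells per row n:   {summary.cells_per_row:.1f}")
print(f"mean cells per col m:   {summary.cells_per_column:.1f}")
print(f"tissue anisotropy sigma:{summary.anisotropy: .2f}   (n/m; target 45/29 = 1.55)")
print(f"mean apical area a:     {summary.mean_area:.2f} um^2 (target 11.68)")
print(f"mean shape ratio s:     {summary.mean_shape:.2f}    (target 1.57)")
print(f"PD-aligned fraction:    {summary.aligned_fraction:.0%}   (target ~52%)")
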