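"""Build the default grating protocol and inspect its structure.

The protocol presents six spatial frequencies, each in one ascending- and
one descending-contrast 18 s block (12 contrasts, one per 1.5 s volume),
with 15 s mean-luminance blanks before every block pair and at the end:
321 s in total. Per-SF contrast grids adapt to the standard CSF so the
sampled contrasts straddle the expected threshold.
"""
from ncsf import build_design, contrast_grid

design = build_design()
print(f"volumes: {design.n_volumes}, duration: {design.duration:g} s, "
      f"TR: {design.tr} s")
print(f"stimulus blocks: {len(design.stimulus_blocks())}, "
      f"blank volumes: {(design.sf_seq == 0).sum()}")
print("block order:", " ".join(design.metadata["block_order"]))

print("\nper-SF contrast grids (%):")
for sf in (0.5, 1, 3, 6, 12, 18):
    g = contrast_grid(sf)
    print(f"  {sf:>4g} c/deg: {g[0]:6.2f} .. {g[-1]:5.1f}  "
          f"({len(g)} log-spaced values)")
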