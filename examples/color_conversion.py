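"""Convert a few 8-bit sRGB colors to Lab / Luv / LCh.

Run: python examples/color_conversion.py
"""

import numpy as np

from chromadiff import srgb_to_lab, srgb_to_lch, srgb_to_luv

colors = {
    "white": (255, 255, 255),
    "mid gray": (128, 128, 128),
    "sRGB red": (255, 0, 0),
    "eosin-like pink": (230, 140, 160),
    "hematoxylin-like blue": (90, 80, 160),
}

print(f"{'color':<22} {'L*':>7} {'a*':>8} {'b*':>8}   {'u*':>8} {'v*':>8}   {'C':>7} {'h deg':>7}")
for name, rgb in colors.items():
    px = np.array([[rgb]], dtype=np.uint8)
    L, a, b = srgb_to_lab(px)[0, 0]
    _, u, v = srgb_to_luv(px)[0, 0]
    _, C, h = srgb_to_lch(px)[0, 0]
    print(f"{name:<22} {L:7.2f} {a:8.2f} {b:8.2f}   {u:8.2f} {v:8.2f}   {C:7.2f} {h:7.2f}")

print()
print("L* is lightness (0 black .. 100 white); a*/b* and u*/v* are opponent")
print("chromaticities (0 for neutral grays); C is chroma and h the hue angle.")
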