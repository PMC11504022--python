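"""Why IoU collapses on tiny boxes and the Wasserstein similarity does not.

Builds the two worked box configurations — a 3x3 microbleed-sized target and
a 24x24 standard target, each with a 1-px localization error — and prints
every similarity in the IoU family next to the normalized Wasserstein
similarity (C = 12.8).
"""

from cmbscreen.boxes import Box, iou_family, nwd_similarity

small = (Box(0, 0, 3, 3), Box(1, 1, 4, 4))       # 3x3 target, 1-px diagonal shift
standard = (Box(0, 0, 24, 24), Box(1, 0, 25, 24))  # 24x24 target, 1-px x shift

print(f"{'measure':<10}{'small 3x3':>12}{'standard 24x24':>16}")
for name in ("iou", "giou", "diou", "ciou"):
    print(f"{name:<10}{iou_family(*small, name):>12.2f}{iou_family(*standard, name):>16.2f}")
print(f"{'nwd':<10}{nwd_similarity(*small):>12.2f}{nwd_similarity(*standard):>16.2f}")

print()
print("The same 1-px annotation jitter costs a 3x3 target two thirds of its IoU")
print("but moves the Wasserstein similarity by < 0.04 — which is why the box")
print("regression loss mixes the NWD term in for 4-32 px microbleed targets.")
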