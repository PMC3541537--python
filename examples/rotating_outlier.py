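"""One outlier rotating away from a perfect line.

Ten points satisfy y = 0.2 x exactly; the last one is replaced by the
line's endpoint rotated by increasing angles.  Pearson's r swings from
+1 to below -0.5; the skipped correlation removes the stray point and
stays at 1 once the rotation is large enough to be detectable.
"""

import numpy as np

from robustcorr import rotating_outlier_demo

print(f"{'angle':>6} {'outlier y':>10} {'pearson r':>10} {'skipped r':>10}")
for angle in range(0, 180, 10):
    try:
        _, y, pr, sk = rotating_outlier_demo(slope=0.2, angle_deg=angle)
    except ValueError:
        continue
    sk_r = f"{sk.r:10.3f}" if np.isfinite(sk.r) else "  undefined"
    print(f"{angle:6d} {y[-1]:10.1f} {pr.r:10.3f} {sk_r}")

print("\nAt 80 degrees the point sits at (9, -393) and Pearson reports "
      "-0.52 on data that are otherwise perfectly collinear; the skipped "
      "estimate stays at 1.  Small rotations (10-20, 150-170 degrees) "
      "remain inside the detection cutoff, so both estimators track the "
      "contaminated value there.")
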