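"""Draw the full cost-effectiveness plane summary to an SVG file.

The figure shows one bubble per study (area proportional to sample
size), the pooled point (X) with its 95% CI box, the pooled ICER ray,
the bootstrap cloud shaded by its 95% wedge arc, and the $50,000/QALY
willingness-to-pay line.
"""

import cemeta as cm

ds = cm.bundled_tricco()
dc = cm.pool_ratio(ds, "cost")
de = cm.pool_ratio(ds, "effect")
point = cm.icer_point(dc, de, wtp=50_000)
cloud = cm.bootstrap_cloud(ds, "ratio", B=500, seed=42)
arc = cm.wedge_ci(cloud, point)

out = "ce_plane.svg"
cm.plot_ce_plane(ds, point, dc, de, cloud, arc,
                 cm.PlaneSpec(wtp_line=50_000, bubble_scale=0.8), out)
print(f"wrote {out}")
print("Most bubbles and nearly the whole cloud sit below the horizontal "
      "axis at positive effectiveness: cost-saving and effective.")
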