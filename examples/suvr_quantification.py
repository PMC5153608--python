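"""Composite SUVR on phantoms and threshold conversion between scales.

Generates a clean amyloid-negative and amyloid-positive phantom, quantifies
both with the six-target composite SUVR, and shows how a PiB positivity
threshold moves across quantification scales.
"""

from hogpet import (
    composite_suvr,
    generate_phantom,
    jagust_to_joshi,
    jagust_to_spap,
    jagust_to_spap_coefficients,
)
from hogpet.phantom import PhantomSpec

for name, uptake in [("amyloid-negative", 1.0), ("amyloid-positive", 1.5)]:
    bundle = generate_phantom(PhantomSpec(uptake_factor=uptake, seed=0))
    report = composite_suvr(bundle.volume, bundle.regions, threshold=1.12)
    print(f"{name} phantom (cortical uptake x{uptake:g}):")
    print(f"  composite SUVR = {report.composite:.3f} "
          f"(threshold {report.threshold}, {'positive' if report.positive else 'negative'})")

# A composite SUVR threshold defined on one quantification scale must be
# converted before use on another; the combined map is the composition of
# two published affine regressions.
t_jagust = 1.465
slope, intercept = jagust_to_spap_coefficients()
print(f"\nPiB threshold {t_jagust} (Jagust scale)")
print(f"  -> Joshi scale: {jagust_to_joshi(t_jagust):.5f}")
print(f"  -> sPAP scale:  {jagust_to_spap(t_jagust):.5f}  (rounds to {jagust_to_spap(t_jagust):.2f})")
print(f"combined map: t_sPAP = {slope} * t_Jagust + {intercept}")
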