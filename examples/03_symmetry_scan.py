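"""Detect rotational pseudo-symmetry by rotational cross-correlation.

Projects a model at 5-degree increments and correlates projections
against each other.  A two-fold model correlates at 180 degrees; an
eight-fold interbead region adds peaks at every 45-degree multiple.
"""

from fibrilscope.phantoms import PhantomSpec, make_microfibril_phantom
from fibrilscope.reconstruct import impose_cn
from fibrilscope.symmetry import (default_regions, detect_symmetry_orders,
                                  extract_region, rotational_correlation_scan)

vol2 = impose_cn(make_microfibril_phantom(PhantomSpec(), 96, 8.0), 2)
curve2 = rotational_correlation_scan(vol2, increment=5.0)
orders2 = detect_symmetry_orders(curve2)
print("full C2 model:  orders", [n for n, _ in orders2],
      "(the 180-degree peak is the two-fold axis)")

spec8 = PhantomSpec(axial_symmetry_order=8)
vol8 = make_microfibril_phantom(spec8, 96, 8.0)
period_vox = spec8.periodicity * 10.0 / 8.0
interbead = extract_region(vol8, period_vox, default_regions()["interbead"])
curve8 = rotational_correlation_scan(interbead, increment=5.0)
orders8 = detect_symmetry_orders(curve8)
print("C8 interbead:   orders", [n for n, _ in orders8],
      "with peaks at", sorted(set(float(a) for _, aa in orders8 for a in aa)))
print("Nested orders (8, 4, 2) arise because every eight-fold peak set "
      "contains the four- and two-fold peak sets.")
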