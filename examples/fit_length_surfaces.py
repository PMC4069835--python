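"""Fit cubic polynomial length surfaces to the synthetic limb.

Sweeps each muscle's spanned joints on an 11-point grid, fits a cubic
polynomial surface to the musculotendon lengths, and reports the coefficient
of determination on held-out midpoint poses.  R^2 near 1 means the cheap
polynomial can stand in for the full geometric path model.
"""

from propriosim import fit_surface, goodness_of_fit
from propriosim.synthetic import (default_synthetic_roster,
                                  generate_sample_table)

for spec in default_synthetic_roster():
    train = generate_sample_table(spec, 11, "length")
    surface = fit_surface(train, spec.spanned_joints)
    held = generate_sample_table(spec, 11, "length", midpoints=True)
    r2 = goodness_of_fit(surface, held)
    print(f"{spec.muscle_id:20s} joints {spec.spanned_joints}: "
          f"{len(surface.coeffs):2d} terms, held-out R^2 = {r2:.5f}")
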