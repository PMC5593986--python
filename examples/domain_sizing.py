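"""Size gel-like nanodomains from a negative diffusion-law intercept.

When the intercept t0 of the transit-time line is negative, the
extrapolated line crosses tau_D = 0 at a positive spot diameter
omega = sqrt(8 ln2 D_eff |t0|) — an estimate of the hindering domain
size.  The two parameter pairs below are regime fits reported for the
slow regions of 1:1 phospholipid:cholesterol bilayers above their
dynamical crossovers; the published sizes are 119 +/- 4 nm and
97 +/- 4 nm.
"""

from spotvar import DomainSizeError, domain_size

for name, D_eff, t0 in [
    ("DOPC:Chl(1:1), slow region, above crossover", 1.14, -2.27),
    ("DMPC:Chl(1:1), slow region, above crossover", 0.96, -1.77),
]:
    omega = domain_size(D_eff, t0)
    print(f"{name}:")
    print(f"  D_eff = {D_eff} um^2/s, t0 = {t0} ms  ->  omega = {omega:.1f} nm")

# the estimator refuses non-negative intercepts: no zero crossing exists
try:
    domain_size(1.0, +0.2)
except DomainSizeError as exc:
    print(f"\npositive intercept refused: {exc}")
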