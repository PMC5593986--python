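"""Reference membrane scenarios for the three diffusion-law signatures.

These are the package's study conditions: a free bilayer, a bilayer with
partitioning slow nanodomains (trapping, positive diffusion-law
intercept) and a bilayer with gel-like exclusion obstacles (negative
intercept).  A permeable square meshwork is also provided for
hop-diffusion studies.  Each entry is a keyword dict for
:func:`spotvar.membrane.build_membrane`.
"""

from __future__ import annotations

FREE_BILAYER = dict(box_edge=2.0, D_out=2.0)

# dynamically partitioning nanodomains acting as transient binding
# sites: the tracer is nearly immobile inside (D_in << D_out), entry is
# rate-limited so occupancy stays moderate, exit is diffusion-limited.
# The quasi-immobile bound fraction adds a spot-size-independent slow
# correlation component -> positive diffusion-law intercept.
TRAPPED_NANODOMAINS = dict(
    box_edge=2.0, D_out=2.0,
    n_domains=200, domain_radius=0.04,
    D_in=0.05, p_enter=0.2, p_exit=1.0,
)

# gel-like obstacles: tracers essentially cannot enter; interstitial
# diffusion is free at short range but obstructed at long range, so the
# large-spot chord of the convex diffusion law has a negative intercept
GEL_DOMAINS = dict(
    box_edge=2.0, D_out=2.0,
    n_domains=60, domain_radius=0.08,
    D_in=2.0, p_enter=0.01, p_exit=1.0,
)

# permeable square meshwork (hop diffusion between compartments)
MESHWORK = dict(box_edge=2.0, D_out=2.0, mesh_size=0.15, p_hop=0.1)

SCENARIOS = {
    "free": FREE_BILAYER,
    "trapped": TRAPPED_NANODOMAINS,
    "gel": GEL_DOMAINS,
    "meshwork": MESHWORK,
}
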