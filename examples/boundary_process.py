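"""Extracting the boundary (last-exit) process from a realized path.

The boundary state W_k is the length-k prefix of the limiting infinite
polymer: the state at the last visit to level k.  Last exits are not
stopping times, so the extraction holds back a safety margin of levels
below the maximum attained level.  The empirical distribution of the
boundary tip types converges to sigma_bar.
"""

import numpy as np

from copolymer import (
    RateParameters,
    cone_frequencies,
    cone_visit_counts,
    cone_visit_fractions,
    extract_boundary,
    limiting_composition,
    simulate_embedded,
)

params = RateParameters(kplus=(2.0, 1.0), kminus=(0.5, 0.5))
path = simulate_embedded(params, n_steps=100_000, seed=99)

bnd = extract_boundary(path, safety_margin=10)
print(f"boundary records: levels 0..{bnd.valid_up_to} "
      f"(path reached level {path.levels().max()})")
print(f"boundary tip frequencies {cone_frequencies(bnd).round(4)}  "
      f"(theory sigma_bar = {limiting_composition(params).round(4)})")

chi, chi_root = cone_visit_counts(path)
n = path.n_steps
print(f"cone-visit fractions    {(chi[-1] / n).round(4)}  "
      f"(theory {cone_visit_fractions(params).round(4)})")
print(f"root visits: {chi_root[-1]} of {n + 1} states")
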