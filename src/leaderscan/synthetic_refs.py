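"""Synthetic stand-in reference sequences for worked examples.

The canonical worked example for the feature pipeline is the human 4EBP2
(EIF4EBP2) 5' leader, described by its published summary descriptors:
297 nt, 75% GC, 35% C, strongly structured.  The real sequence is not
bundled here; ``synthetic_4ebp2_like_leader`` constructs a SYNTHETIC
stand-in with exactly those length and composition descriptors (to the
printed integer precision) so that the composition/length code paths can
be exercised against known values.  Its minimum free energy is whatever
the folding engine computes for the arrangement — it is NOT the real
leader's MFE and must not be compared against it.
"""

from __future__ import annotations

import numpy as np

# Base counts chosen so the rounded percentages equal the printed
# descriptors: GC = (119+104)/297 = 75.08% -> 75; C = 104/297 = 35.02% -> 35.
_COUNTS = {"G": 119, "C": 104, "A": 37, "T": 37}
_SHUFFLE_SEED = 1999


def synthetic_4ebp2_like_leader() -> str:
    """A synthetic 297-nt leader with 75% GC and 35% C (stand-in).

    Deterministic: the fixed base multiset is shuffled with a frozen seed.
    """
    bases = [b for b, n in sorted(_COUNTS.items()) for _ in range(n)]
    rng = np.random.default_rng(_SHUFFLE_SEED)
    rng.shuffle(bases)
    return "".join(bases)
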