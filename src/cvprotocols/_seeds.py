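"""Deterministic seed derivation shared by every randomised component.

All pseudo-randomness in the package flows from a single base seed through
:func:`derive_seed`, so a whole run (any number of repeats, outer folds,
workers) is a pure function of its base seed and is independent of execution
order.
"""

import numpy as np

_TAGS = {"repeat": 1, "outer": 2, "inner": 3, "fold": 4, "dcv": 5, "data": 6}


def derive_seed(base_seed: int, *parts) -> int:
    """Derive a child seed from a base seed and a path of tags/indices.

    Parts may be small non-negative ints or one of the registered string tags.
    The same path always yields the same child seed; distinct paths collide
    only with SeedSequence's (negligible) hash-collision probability.
    """
    key = [int(base_seed)]
    for p in parts:
        key.append(_TAGS[p] if isinstance(p, str) else int(p))
    ss = np.random.SeedSequence(key)
    return int(ss.generate_state(1, np.uint32)[0])
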