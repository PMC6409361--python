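"""Deterministic seed derivation.

Every source of randomness in the package descends from a single integer
seed through :func:`derive_seed`, so adding a stage to a pipeline never
perturbs the random draws of earlier stages.
"""

from __future__ import annotations

import hashlib


def derive_seed(root_seed: int, *tokens: object) -> int:
    """Derive a child seed from ``root_seed`` and a sequence of stage tokens.

    The derivation hashes the textual representation of the tokens with
    SHA-256 and folds the digest into a non-negative integer below 2**31,
    which every downstream RNG constructor accepts.
    """
    payload = repr((int(root_seed),) + tokens).encode()
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
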