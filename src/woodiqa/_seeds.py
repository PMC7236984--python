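"""Deterministic seed derivation.

One top-level integer seed fans out to per-stage and per-image seeds via a
stated hash so that dataset manifests are reproducible while every image
receives an independent noise field.
"""

import hashlib


def derive_seed(master_seed: int, *tokens) -> int:
    """Derive a child seed < 2**31 from a master seed and string tokens.

    The derivation is SHA-256 of ``"<master_seed>:<token>:<token>..."``
    truncated to 31 bits; it is stable across platforms and sessions.
    """
    key = ":".join([str(int(master_seed))] + [str(t) for t in tokens])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
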