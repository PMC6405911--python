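"""Deterministic seed derivation.

All randomness in the pipeline flows from one master seed.  Child seeds
are derived through :class:`numpy.random.SeedSequence`, which is stable
across processes and platforms (unlike Python's salted ``hash``).
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(*parts) -> int:
    """Stable 31-bit child seed from a master seed plus context labels."""
    entropy = [p if isinstance(p, (int, np.integer))
               else zlib.crc32(str(p).encode())
               for p in parts]
    ss = np.random.SeedSequence([int(e) & 0xFFFFFFFF for e in entropy])
    return int(ss.generate_state(1)[0] % (2 ** 31))
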