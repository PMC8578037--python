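"""Named random substreams derived from one master seed.

Every stochastic stage of the pipeline (rewiring nulls, permutation
schedules, modularity restarts, resilience reps, cohort simulation) draws
from its own independent stream so that stages can be re-run or reordered
without perturbing each other.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named stream under ``master_seed``.

    The stream key is a CRC32 of the stage name, so streams are stable
    across runs and platforms; the master seed itself stays below 2**31.
    """
    if not (0 <= int(master_seed) < 2**31):
        raise ValueError("master seed must be in [0, 2**31)")
    key = zlib.crc32(name.encode("utf-8")) & 0xFFFFFFFF
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(key,))
    return np.random.Generator(np.random.PCG64(ss))
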