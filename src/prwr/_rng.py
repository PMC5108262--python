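"""Seed derivation for reproducible multi-replicate experiments.

A single master seed must drive every source of randomness in an
experiment — the q% site splits, the forest fits, and the tie-breaking
shuffles — such that re-running with the same master seed is byte-identical
while replicates remain statistically independent of one another.

The scheme is a counter construction over :class:`numpy.random.SeedSequence`:
each consumer passes the master seed plus a tuple of small integers naming
its position in the experiment (e.g. ``(q_index, replicate, stage)``), and
receives a 31-bit child seed.  SeedSequence guarantees well-separated
streams for distinct keys; the 31-bit reduction keeps seeds usable by every
downstream library (scikit-learn requires seeds below 2**32).
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_seed", "spawn_rng"]

# stage tags so distinct stages of one replicate never share a stream
STAGE_SPLIT = 0
STAGE_MODEL = 1
STAGE_TIEBREAK = 2


def child_seed(master_seed: int, *key: int) -> int:
    """Derive a deterministic 31-bit seed from a master seed and a key path.

    Parameters
    ----------
    master_seed
        The experiment-level seed supplied by the user.
    *key
        Non-negative integers identifying the consumer (replicate index,
        stage tag, ...). Distinct key tuples yield independent streams.
    """
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def spawn_rng(master_seed: int, *key: int) -> np.random.Generator:
    """A :class:`numpy.random.Generator` seeded by :func:`child_seed`."""
    return np.random.default_rng(child_seed(master_seed, *key))
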