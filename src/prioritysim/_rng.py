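"""Deterministic random-stream management.

All randomness in a run derives from a single master seed.  Streams are split
by (purpose label, replicate index): the stream id is the CRC32 hash of the
purpose label together with the replicate index, fed to a ``SeedSequence``
spawn key.  Policy identity never enters seed derivation, so runs of
different policies at the same replicate share epidemiological random numbers
(common random numbers).

Draws whose *order* of consumption depends on policy (consumable checks,
effectiveness draws, queue tiebreaks) use :func:`substream`, which keys an
independent generator on stable episode coordinates (person, treatment, day)
instead of on scan order.
"""

from __future__ import annotations

import zlib

import numpy as np


def _label_key(label: str) -> int:
    return zlib.crc32(label.encode("utf8"))


def stream(master_seed: int, label: str, replicate: int = 0) -> np.random.Generator:
    """Return the generator for one purpose label within one replicate."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(_label_key(label), replicate))
    return np.random.Generator(np.random.PCG64(ss))


def substream(
    master_seed: int,
    label: str,
    replicate: int,
    person_id: int,
    key: str,
    day: int,
) -> np.random.Generator:
    """Per-episode generator independent of queue scan order.

    ``key`` is typically a treatment id; the generator is fully determined by
    the coordinates, so any two policies that deliver the same HSI to the same
    person on the same day observe identical consumable/effectiveness draws.
    """
    ss = np.random.SeedSequence(
        master_seed,
        spawn_key=(_label_key(label), replicate, person_id, _label_key(key), day),
    )
    return np.random.Generator(np.random.PCG64(ss))


def derived_seed(master_seed: int, label: str, replicate: int = 0) -> int:
    """Collapse a stream identity into a single integer seed."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(_label_key(label), replicate))
    return int(ss.generate_state(1, dtype=np.uint64)[0])
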