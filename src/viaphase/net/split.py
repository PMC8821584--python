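"""Sequence-level train/validation/test splitting.

Splitting is done by time-lapse sequence, never by frame, so that frames
of one recording cannot leak across partitions.  Counts follow the
requested ratio (default 6:1:1) with largest-remainder rounding and at
least one sequence per partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class SequenceSplit:
    train: tuple
    validation: tuple
    test: tuple

    def __post_init__(self) -> None:
        parts = (set(self.train), set(self.validation), set(self.test))
        total = len(self.train) + len(self.validation) + len(self.test)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValueError("split partitions must be disjoint")


def split_sequences(sequence_ids: Sequence, ratios=(6, 1, 1), seed: int = 0) -> SequenceSplit:
    """Randomly partition sequence ids into train/validation/test.

    Largest-remainder allocation of ``len(ids)`` among ``ratios``; every
    partition receives at least one sequence (taking from the largest
    partition if rounding left one empty).  Deterministic for a fixed seed.
    """
    ids = list(sequence_ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 sequences to form a 3-way split")
    if len(set(ids)) != len(ids):
        raise ValueError("sequence ids must be unique")
    ratios = np.asarray(ratios, dtype=float)
    if ratios.shape != (3,) or np.any(ratios <= 0):
        raise ValueError("ratios must be 3 positive numbers")

    n = len(ids)
    quota = n * ratios / ratios.sum()
    counts = np.floor(quota).astype(int)
    remainders = quota - counts
    for _ in range(n - counts.sum()):
        k = int(np.argmax(remainders))
        counts[k] += 1
        remainders[k] = -1.0
    while np.any(counts == 0):
        counts[int(np.argmax(counts))] -= 1
        counts[int(np.argmin(counts))] += 1

    order = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in order]
    a, b = counts[0], counts[0] + counts[1]
    return SequenceSplit(train=tuple(shuffled[:a]),
                         validation=tuple(shuffled[a:b]),
                         test=tuple(shuffled[b:]))
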