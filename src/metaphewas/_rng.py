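"""Named-substream random number generation.

All stochastic components derive their generators from a single master seed
plus a tuple of string/int labels (e.g. ``("geno", cohort, snp)``).  Adding a
new endpoint or SNP to a configuration therefore never perturbs the draws of
existing ones, and the same (seed, labels) pair is reproducible across runs
and platforms.
"""

from __future__ import annotations

import zlib

import numpy as np


def _label_to_int(label: object) -> int:
    if isinstance(label, (int, np.integer)):
        return int(label) & 0xFFFFFFFF
    return zlib.crc32(str(label).encode("utf-8"))


def substream(master_seed: int, *labels: object) -> np.random.Generator:
    """Return a Generator for the substream identified by ``labels``.

    The stream is a pure function of ``(master_seed, labels)``: crc32 hashes
    of the labels are appended to the master seed as SeedSequence entropy.
    """
    entropy = [int(master_seed) & 0x7FFFFFFF] + [_label_to_int(l) for l in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def as_rng(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    """Coerce an integer seed or an existing Generator to a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(int(seed_or_rng))
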