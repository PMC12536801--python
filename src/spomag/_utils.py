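"""Shared helpers: seed derivation, hashing, logging."""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

log = logging.getLogger("spomag")

#: Binary phenotype labels. ``Sporulating`` is the positive class everywhere.
POSITIVE_LABEL = "Sporulating"
NEGATIVE_LABEL = "Non-Sporulating"
PHENOTYPES = (POSITIVE_LABEL, NEGATIVE_LABEL)


def derive_seed(master_seed: int, stream: str) -> int:
    """Derive a sub-seed below 2**31 from a master seed and a stream name.

    One user-facing seed fans out deterministically to every stochastic
    component (partitioning, CV folds, bootstraps, simulators, samplers).
    """
    digest = hashlib.sha256(f"{master_seed}:{stream}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
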