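"""Small shared helpers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def random_dna(rng, length: int) -> str:
    """Uniform random DNA string of the given length."""
    return _BASE_ARR[rng.integers(0, 4, int(length))].tobytes().decode()


def sha256_bytes(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def sha256_file(path) -> str:
    return sha256_bytes(Path(path).read_bytes())


def dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_json(path):
    return json.loads(Path(path).read_text())
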