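"""Shared helpers: seed derivation, stamped table output, config hashing."""

from __future__ import annotations

import hashlib
import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

PACKAGE_VERSION = "0.1.0"

__all__ = ["child_seed", "config_hash", "write_table", "rng_from"]


def child_seed(master_seed: int, stage: str) -> int:
    """Derive a named, reproducible child seed from a master seed.

    The derivation is ``crc32(stage) XOR (master * 2654435761)`` reduced
    mod 2**31, so every stage of a run gets an independent stream that can
    be re-created in isolation from the master seed and the stage name.
    """
    mix = (int(master_seed) * 2654435761) % (2**31)
    return (zlib.crc32(stage.encode("utf-8")) ^ mix) % (2**31)


def rng_from(master_seed: int, stage: str) -> np.random.Generator:
    """Generator seeded with the named child seed of *master_seed*."""
    return np.random.default_rng(child_seed(master_seed, stage))


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration mapping."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode("utf-8")
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    *,
    seed: int | None = None,
    cfg_hash: str | None = None,
    index: bool = True,
) -> Path:
    """Write *df* as TSV with a header comment recording provenance.

    The comment line carries package version, configuration hash and RNG
    seed so every result table is self-describing.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"# ecoassembly={PACKAGE_VERSION} config={cfg_hash or 'NA'} seed={seed if seed is not None else 'NA'}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=index)
    return path


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (skips comment lines)."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
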