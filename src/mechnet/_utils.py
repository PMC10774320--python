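"""Internal validation and seeding helpers."""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd


def validate_expression(expr: pd.DataFrame, min_samples: int = 1, name: str = "expression") -> pd.DataFrame:
    """Check a genes x samples frame: unique ids, finite numeric values."""
    if not isinstance(expr, pd.DataFrame):
        raise TypeError(f"{name} must be a pandas DataFrame (genes x samples)")
    if expr.shape[0] == 0 or expr.shape[1] == 0:
        raise ValueError(f"{name} is empty")
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"{name}: duplicate gene ids {dups}")
    if expr.columns.has_duplicates:
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()[:5]
        raise ValueError(f"{name}: duplicate sample ids {dups}")
    if expr.shape[1] < min_samples:
        raise ValueError(f"{name}: needs >= {min_samples} samples, got {expr.shape[1]}")
    values = expr.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise TypeError(f"{name}: values must be numeric")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{name}: non-finite values present")
    return expr


def derived_rng(seed: int, *keys: str) -> np.random.Generator:
    """Generator seeded by ``seed`` plus stable hashes of string keys.

    Keyed derivation (rather than positional spawning) keeps per-entity
    randomness identical when entities are reordered.
    """
    entropy = [int(seed)] + [zlib.crc32(str(k).encode("utf8")) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
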