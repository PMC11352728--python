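"""Alternative ligand/substrate encodings: ECFP, one-hot and random controls.

These are the cheap baselines the DFT-derived descriptors are benchmarked
against. The random-descriptor control mirrors the negative-control design
in which each ligand is consistently represented by the same vector of 34
uniform values in [-100, 100]: any predictive power it shows can only come
from object identity, never from chemistry.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["circular_fingerprint", "one_hot", "random_descriptors"]


def circular_fingerprint(mol_input, radius: int = 2, n_bits: int = 512) -> np.ndarray:
    """Morgan (ECFP) bit vector; radius 2 with 512 bits reproduces ECFP4."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    if isinstance(mol_input, str):
        mol = Chem.MolFromSmiles(mol_input)
        if mol is None:
            raise ValueError(f"unparsable SMILES {mol_input!r}")
    else:
        mol = mol_input
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return np.array(fp, dtype=np.uint8)


def one_hot(ids: Sequence[str]) -> pd.DataFrame:
    """Indicator matrix, one row per input id; columns = sorted unique ids."""
    ids = [str(i) for i in ids]
    columns = sorted(set(ids))
    data = np.zeros((len(ids), len(columns)), dtype=np.uint8)
    col_index = {c: k for k, c in enumerate(columns)}
    for row, i in enumerate(ids):
        data[row, col_index[i]] = 1
    return pd.DataFrame(data, columns=columns)


def random_descriptors(
    ids: Sequence[str],
    n_features: int = 34,
    low: float = -100.0,
    high: float = 100.0,
    seed: int = 0,
) -> pd.DataFrame:
    """One uniform random vector per unique id, reproducible per seed.

    Every occurrence of an id maps to the same vector; unique ids are
    processed in sorted order so the mapping is independent of input order.
    """
    if n_features <= 0:
        raise ValueError("n_features must be positive")
    unique = sorted({str(i) for i in ids})
    rng = np.random.default_rng(seed)
    matrix = rng.uniform(low, high, size=(len(unique), n_features))
    return pd.DataFrame(
        matrix, index=pd.Index(unique, name="id"),
        columns=[f"rand_{k + 1}" for k in range(n_features)],
    )
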