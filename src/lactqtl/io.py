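"""CSV dialects for study inputs and outputs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .linkage import LinkageMap, TransmissionMatrix

PHENOTYPE_COLUMNS = ["ewe_id", "lactation_id", "day", "trait", "value"]


def read_phenotypes(path) -> pd.DataFrame:
    """Long-format phenotype records (ewe_id, lactation_id, day, trait, value)."""
    df = pd.read_csv(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file missing columns: {missing}")
    df["day"] = df["day"].astype(int)
    df["value"] = df["value"].astype(float)
    if (df["day"] < 1).any():
        raise ValueError("day in milk must be >= 1")
    if (df["value"] < 0).any():
        raise ValueError("phenotype values must be nonnegative")
    return df


def read_map(path) -> LinkageMap:
    return LinkageMap.from_csv(path)


def read_genotypes(path) -> TransmissionMatrix:
    return TransmissionMatrix.from_csv(path)


def read_trait_values(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_wood_fits(fits: pd.DataFrame, path) -> None:
    fits.to_csv(path, index=False)


def write_table(df: pd.DataFrame, path, index=False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)
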