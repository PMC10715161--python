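"""Core in-memory containers shared by every stage of the pipeline.

The universal currency is the :class:`AbundanceTable`, a samples x taxa
matrix of counts or relative abundances with an optional taxonomy map.
Pairwise dissimilarities travel as :class:`skbio.DistanceMatrix` and
phylogenies as :class:`skbio.TreeNode`; this module only adds the thin
domain types the pipeline itself defines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "TestResult",
    "FormatError",
    "SchemaError",
    "ConfigError",
]


class FormatError(ValueError):
    """A file or matrix violates the expected format."""


class SchemaError(ValueError):
    """A table is missing required columns or carries illegal values."""


class ConfigError(ValueError):
    """A configuration value is inconsistent or out of range."""


_ROW_SUM_TOL = 1e-9


@dataclass
class AbundanceTable:
    """Sample-by-taxon abundance matrix.

    Parameters
    ----------
    data
        DataFrame with samples as the index and taxa as columns. Entries
        must be non-negative and finite.
    kind
        Either ``"counts"`` (raw or rarefied reads) or ``"relative"``
        (rows sum to 1).
    taxonomy
        Optional map taxon_id -> lineage string (rank labels separated by
        ``;`` ordered root-to-leaf, e.g. ``"Bacteria;Bacteroidota;...;Prevotella"``).
    """

    data: pd.DataFrame
    kind: str = "counts"
    taxonomy: Mapping[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "relative"):
            raise SchemaError(f"kind must be 'counts' or 'relative', got {self.kind!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise FormatError(f"duplicate taxon ids: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("abundance matrix contains non-numeric cells")
        if not np.isfinite(values).all():
            raise FormatError("abundance matrix contains non-finite cells")
        if (values < 0).any():
            raise FormatError("abundance matrix contains negative entries")
        if self.kind == "relative":
            sums = values.sum(axis=1)
            bad = np.abs(sums - 1.0) > _ROW_SUM_TOL
            if bad.any():
                raise SchemaError(
                    "relative table rows must sum to 1; offending samples: "
                    f"{self.data.index[bad].tolist()}"
                )

    # -- convenience views -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=1)

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[list(sample_ids)].copy(),
                              kind=self.kind, taxonomy=self.taxonomy)

    def copy(self) -> "AbundanceTable":
        return AbundanceTable(self.data.copy(), kind=self.kind, taxonomy=self.taxonomy)


@dataclass
class TestResult:
    """A single hypothesis-test outcome (chi-square, H, U/Z, F, pseudo-F...)."""

    method: str
    statistic: float
    p_value: float
    df: float | None = None
    permutations: int | None = None
    effect_size: float | None = None
    note: str | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": None if self.statistic is None else float(self.statistic),
            "p_value": None if self.p_value is None else float(self.p_value),
            "df": self.df,
            "permutations": self.permutations,
            "effect_size": None if self.effect_size is None else float(self.effect_size),
            "note": self.note,
        }
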