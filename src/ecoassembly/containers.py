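"""Core in-memory containers for OTU-table ecology.

The three objects every analysis stage consumes:

* :class:`CommunityTable` — nonnegative integer OTU × sample counts,
* :class:`EnvironmentDesign` — sample → environment mapping plus numeric
  covariates (e.g. pH, soil organic carbon),
* :class:`DissimilarityMatrix` — a symmetric pairwise matrix over a fixed
  id set (Bray–Curtis, cophenetic distances, βNTI, Raup–Crick, ...).

Phylogenies are represented by :class:`skbio.TreeNode`; see
:func:`ecoassembly.io.read_tree` for the validation applied on input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CommunityTable", "EnvironmentDesign", "DissimilarityMatrix"]


def _check_unique(values, what: str) -> None:
    idx = pd.Index(values)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass(frozen=True)
class CommunityTable:
    """OTU × sample count table.

    Parameters
    ----------
    counts
        DataFrame with OTU ids as the index and sample ids as the columns.
        Cells must be nonnegative integers (exact-integer floats are
        accepted and coerced).
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if not isinstance(df, pd.DataFrame):
            raise TypeError("counts must be a pandas DataFrame")
        _check_unique(df.index, "OTU ids")
        _check_unique(df.columns, "sample ids")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)):
                raise ValueError("counts contain non-finite values")
            if np.any(values != np.floor(values)):
                raise ValueError("counts must be integers")
        if values.size and values.min() < 0:
            raise ValueError("counts must be nonnegative")
        coerced = df.astype(np.int64)
        coerced.index = coerced.index.astype(str)
        coerced.columns = coerced.columns.astype(str)
        object.__setattr__(self, "counts", coerced)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def matrix(self) -> np.ndarray:
        """Counts as an ``(n_otus, n_samples)`` int array (copy)."""
        return self.counts.to_numpy()

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def otu_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def select_samples(self, sample_ids) -> "CommunityTable":
        return CommunityTable(self.counts.loc[:, list(sample_ids)])

    def select_otus(self, otu_ids) -> "CommunityTable":
        return CommunityTable(self.counts.loc[list(otu_ids), :])

    def __eq__(self, other) -> bool:
        if not isinstance(other, CommunityTable):
            return NotImplemented
        return self.counts.equals(other.counts)


@dataclass(frozen=True)
class EnvironmentDesign:
    """Sample metadata: environment labels and numeric covariates.

    ``frame`` is indexed by sample id and must carry an ``environment``
    column; any numeric columns are treated as covariates (units as
    supplied). An environment is typically one site × treatment cell.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        if not isinstance(df, pd.DataFrame):
            raise TypeError("frame must be a pandas DataFrame")
        _check_unique(df.index, "sample ids")
        if "environment" not in df.columns:
            raise ValueError("metadata must define an 'environment' column")
        if df["environment"].isna().any():
            bad = df.index[df["environment"].isna()].tolist()
            raise ValueError(f"samples with missing environment label: {bad[:5]}")
        df = df.copy()
        df.index = df.index.astype(str)
        df["environment"] = df["environment"].astype(str)
        object.__setattr__(self, "frame", df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def environments(self) -> list[str]:
        """Environment labels in order of first appearance."""
        return list(dict.fromkeys(self.frame["environment"]))

    @property
    def n_environments(self) -> int:
        return len(self.environments)

    def environment_of(self, sample_ids=None) -> pd.Series:
        env = self.frame["environment"]
        if sample_ids is None:
            return env
        missing = [s for s in sample_ids if s not in env.index]
        if missing:
            raise KeyError(f"samples absent from metadata: {missing[:5]}")
        return env.loc[list(sample_ids)]

    def covariates(self) -> pd.DataFrame:
        """Numeric covariate columns (may be empty)."""
        num = self.frame.select_dtypes(include=[np.number])
        return num

    def samples_in(self, environment: str) -> list[str]:
        env = self.frame["environment"]
        return list(env.index[env == environment])

    def grouping(self, key: str) -> pd.Series:
        """Per-sample group labels for ``key`` ('environment' or a column name)."""
        if key == "environment":
            return self.frame["environment"]
        if key not in self.frame.columns:
            raise KeyError(f"metadata has no column {key!r}")
        return self.frame[key].astype(str)


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric pairwise matrix over an ordered id set.

    The diagonal must be zero (NaN allowed for degenerate standardized
    scores). Off-diagonal values may be negative — βNTI and Raup–Crick
    matrices are signed; distance matrices are checked for nonnegativity
    by their producers, not here.
    """

    ids: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.ids)
        _check_unique(ids, "matrix ids")
        values = np.asarray(self.values, dtype=float)
        n = len(ids)
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} does not match {n} ids")
        if not np.allclose(values, values.T, equal_nan=True):
            raise ValueError("matrix is not symmetric")
        diag = np.diag(values)
        if not np.all(np.isnan(diag) | (diag == 0.0)):
            raise ValueError("matrix diagonal must be zero")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "values", values)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DissimilarityMatrix":
        if list(frame.index) != list(frame.columns):
            raise ValueError("matrix index and columns must match")
        return cls(tuple(frame.index), frame.to_numpy(dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.copy(), index=list(self.ids),
                            columns=list(self.ids))

    def reindex(self, ids) -> "DissimilarityMatrix":
        """Restrict/reorder to ``ids`` (all must be present)."""
        ids = [str(i) for i in ids]
        pos = {v: k for k, v in enumerate(self.ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise KeyError(f"ids absent from matrix: {missing[:5]}")
        take = np.array([pos[i] for i in ids])
        return DissimilarityMatrix(tuple(ids), self.values[np.ix_(take, take)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in scipy ``squareform`` order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape
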