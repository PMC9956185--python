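"""Labelled symmetric pairwise matrices over samples (or taxa)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: matrix kinds with a zero diagonal and non-negative entries
_DISSIMILARITY_KINDS = frozenset({"braycurtis", "geographic_km", "phylo_patristic"})
#: all recognised kinds
KINDS = _DISSIMILARITY_KINDS | {"bnti", "rcbray"}

_SYM_TOL = 1e-12


@dataclass
class PairwiseMatrix:
    """A symmetric matrix whose rows/columns are identified by labels.

    Parameters
    ----------
    labels:
        Ordered, unique identifiers for the rows (and columns).
    values:
        Square symmetric array aligned with ``labels``.
    kind:
        One of :data:`KINDS`.  Dissimilarity kinds (``braycurtis``,
        ``geographic_km``, ``phylo_patristic``) must have a zero diagonal
        and non-negative entries; ``braycurtis`` is additionally bounded
        by [0, 1].
    """

    labels: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}; expected one of {sorted(KINDS)}")
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in PairwiseMatrix")
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=_SYM_TOL, rtol=0.0, equal_nan=True):
            raise ValueError("matrix is not symmetric within 1e-12")
        if self.kind in _DISSIMILARITY_KINDS:
            if not np.allclose(np.diag(self.values), 0.0, atol=_SYM_TOL):
                raise ValueError(f"{self.kind} matrix must have a zero diagonal")
            if np.nanmin(self.values) < -_SYM_TOL:
                raise ValueError(f"{self.kind} matrix must be non-negative")
        if self.kind == "braycurtis" and np.nanmax(self.values) > 1.0 + 1e-9:
            raise ValueError("braycurtis values must lie in [0, 1]")

    # -- accessors ---------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not present in matrix") from None

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries (i < j) in row-major order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def pair_labels(self) -> list[tuple[str, str]]:
        iu, ju = np.triu_indices(self.n, k=1)
        return [(self.labels[i], self.labels[j]) for i, j in zip(iu, ju)]

    def subset(self, labels: list[str]) -> "PairwiseMatrix":
        """Reorder/restrict to ``labels`` (all must be present)."""
        idx = [self.index_of(l) for l in labels]
        return PairwiseMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)

    # -- round trip --------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def read_tsv(cls, path, kind: str) -> "PairwiseMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: row and column labels differ")
        return cls(list(df.index), df.to_numpy(dtype=float), kind)
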