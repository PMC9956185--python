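"""Reading, validation, filtering and normalisation of the tabular inputs.

Formats handled here:

* OTU table — TSV, taxa as rows and samples as columns (or transposed),
  first column holds taxon identifiers, header row holds sample ids.
* Sample metadata — CSV with mandatory columns ``sample_id``, ``site_id``,
  ``layer``, ``latitude``, ``longitude``; every other numeric column is
  treated as an environmental variable.
* Taxonomy assignments — TSV with columns ``taxon_id``, ``lineage``,
  ``percent_identity``, ``percent_coverage``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LAYERS = ("surface", "bottom")

#: record-level filter defaults: strict > 90 for both identity and coverage
DEFAULT_MIN_IDENTITY = 90.0
DEFAULT_MIN_COVERAGE = 90.0
#: pooled relative abundance above which a group is reported individually
DEFAULT_DOMINANCE_THRESHOLD = 0.01
#: dissolved-oxygen level (mg/L) below which a sample counts as hypoxic
DEFAULT_HYPOXIA_MG_L = 2.0

_REL_TOL = 1e-9


class TableParseError(ValueError):
    """A cell of an input table could not be parsed."""


class ValidationError(ValueError):
    """An input violated a structural invariant."""


# ---------------------------------------------------------------------------
# OTU table
# ---------------------------------------------------------------------------


@dataclass
class OTUTable:
    """Taxa x samples abundance matrix.

    ``counts`` is a dense float array with shape
    ``(len(taxon_ids), len(sample_ids))``.  When ``is_relative`` is set each
    sample column sums to 1 (within 1e-9).
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    is_relative: bool = False

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts, dtype=float)
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            dup = _first_duplicate(self.taxon_ids)
            raise ValidationError(f"duplicate taxon id {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise ValidationError(f"duplicate sample id {dup!r}")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("counts contain non-finite values")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if self.is_relative:
            sums = self.counts.sum(axis=0)
            bad = np.where(np.abs(sums - 1.0) > _REL_TOL)[0]
            if bad.size:
                raise ValidationError(
                    f"relative table column {self.sample_ids[bad[0]]!r} sums to "
                    f"{sums[bad[0]]!r}, expected 1"
                )

    # -- basic accessors ----------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in table") from None

    def sample(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_index(sample_id)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    def select_samples(self, sample_ids: list[str]) -> "OTUTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return OTUTable(self.taxon_ids, list(sample_ids), self.counts[:, idx], self.is_relative)

    def select_taxa(self, taxon_ids: list[str]) -> "OTUTable":
        pos = {t: i for i, t in enumerate(self.taxon_ids)}
        missing = [t for t in taxon_ids if t not in pos]
        if missing:
            raise KeyError(f"taxa not in table: {missing[:5]}")
        idx = [pos[t] for t in taxon_ids]
        return OTUTable(list(taxon_ids), self.sample_ids, self.counts[idx, :], self.is_relative)

    def drop_empty_taxa(self) -> "OTUTable":
        keep = self.counts.sum(axis=1) > 0
        return OTUTable(
            [t for t, k in zip(self.taxon_ids, keep) if k],
            self.sample_ids,
            self.counts[keep, :],
            self.is_relative,
        )

    # -- I/O -----------------------------------------------------------------

    def write_tsv(self, path, index_label: str = "taxon_id") -> None:
        # %.17g round-trips IEEE doubles exactly
        self.to_dataframe().to_csv(path, sep="\t", index_label=index_label, float_format="%.17g")

    @classmethod
    def read_tsv(cls, path, orientation: str = "auto") -> "OTUTable":
        """Read a tab-separated OTU table.

        ``orientation`` is one of ``taxa_rows``, ``samples_rows`` or ``auto``.
        Auto-detection looks at the header of the first column: a label that
        mentions "sample" selects ``samples_rows``, anything else (including
        an empty label or one mentioning otu/taxon) selects ``taxa_rows``.
        """
        if orientation not in ("auto", "taxa_rows", "samples_rows"):
            raise ValueError(f"unknown orientation {orientation!r}")
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        if orientation == "auto":
            corner = str(df.index.name or "")
            if re.search(r"sample", corner, flags=re.IGNORECASE):
                orientation = "samples_rows"
            else:
                orientation = "taxa_rows"
        if orientation == "samples_rows":
            df = df.T
        values = np.empty(df.shape, dtype=float)
        for j, col in enumerate(df.columns):
            try:
                # numpy's parser is correctly rounded; pandas' fast path is not
                values[:, j] = df[col].to_numpy(dtype=str).astype(np.float64)
            except (ValueError, TypeError):
                bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
                row = bad.index[0] if len(bad) else "?"
                raise TableParseError(
                    f"{path}: malformed numeric cell at row {row!r}, column {col!r}"
                ) from None
        return cls(list(df.index), list(df.columns), values)


def read_otu_table(path, orientation: str = "auto") -> OTUTable:
    """Functional alias for :meth:`OTUTable.read_tsv`."""
    return OTUTable.read_tsv(path, orientation=orientation)


def to_relative(table: OTUTable) -> OTUTable:
    """Divide each sample column by its sum.

    Idempotent on already-relative tables.  A sample whose column sums to
    zero is an error (it cannot be normalised).
    """
    sums = table.counts.sum(axis=0)
    zero = np.where(sums <= 0)[0]
    if zero.size:
        raise ValidationError(
            f"sample {table.sample_ids[zero[0]]!r} has zero total abundance"
        )
    return OTUTable(table.taxon_ids, table.sample_ids, table.counts / sums, is_relative=True)


def average_samples(table: OTUTable, groups: dict[str, str]) -> OTUTable:
    """Average sample columns that share a group key (e.g. PCR replicates).

    ``groups`` maps sample id -> group id; samples absent from the map are
    kept as singleton groups under their own id.  Output sample order follows
    first appearance in the input.
    """
    keys = [groups.get(s, s) for s in table.sample_ids]
    order: list[str] = []
    members: dict[str, list[int]] = {}
    for i, k in enumerate(keys):
        if k not in members:
            members[k] = []
            order.append(k)
        members[k].append(i)
    cols = np.column_stack([table.counts[:, members[k]].mean(axis=1) for k in order])
    out = OTUTable(table.taxon_ids, order, cols, table.is_relative)
    return out


def _first_duplicate(items: list[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

REQUIRED_METADATA_COLUMNS = ("sample_id", "site_id", "layer", "latitude", "longitude")


class SampleMetadata:
    """Per-sample site, layer, coordinates and environmental variables.

    Backed by a :class:`pandas.DataFrame` indexed by ``sample_id``.  Any
    column beyond the mandatory five (plus an optional ``replicate``) is an
    environmental variable; missing values stay as NaN and are excluded
    pairwise by downstream statistics.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate sample id {dup!r} in metadata")
        bad_layer = set(df["layer"].astype(str)) - set(LAYERS)
        if bad_layer:
            raise ValidationError(f"layer must be one of {LAYERS}; got {sorted(bad_layer)}")
        lat = pd.to_numeric(df["latitude"], errors="raise")
        lon = pd.to_numeric(df["longitude"], errors="raise")
        if (lat.abs() > 90).any():
            raise ValidationError("latitude outside [-90, 90]")
        if (lon.abs() > 180).any():
            raise ValidationError("longitude outside [-180, 180]")
        df["latitude"] = lat
        df["longitude"] = lon
        self.df = df.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def env_vars(self) -> list[str]:
        skip = set(REQUIRED_METADATA_COLUMNS) | {"replicate"}
        out = []
        for c in self.df.columns:
            if c in skip:
                continue
            if pd.api.types.is_numeric_dtype(self.df[c]):
                out.append(c)
        return out

    def get(self, variable: str) -> pd.Series:
        if variable not in self.df.columns:
            raise KeyError(f"metadata has no variable {variable!r}")
        return self.df[variable]

    def layer_of(self, sample_id: str) -> str:
        return str(self.df.loc[sample_id, "layer"])

    def samples_in_layer(self, layer: str) -> list[str]:
        if layer == "all":
            return self.sample_ids
        if layer not in LAYERS:
            raise ValueError(f"unknown layer {layer!r}")
        return list(self.df.index[self.df["layer"] == layer])

    def subset(self, sample_ids: list[str]) -> "SampleMetadata":
        return SampleMetadata(self.df.loc[list(sample_ids)].reset_index(drop=True))

    def coordinates(self) -> np.ndarray:
        return self.df[["latitude", "longitude"]].to_numpy(dtype=float)

    def write_csv(self, path) -> None:
        self.df.reset_index(drop=True).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "SampleMetadata":
        return cls(pd.read_csv(path))

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# Taxonomy records and record-level filters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaxonomyRecord:
    taxon_id: str
    lineage: str
    percent_identity: float
    percent_coverage: float

    def __post_init__(self) -> None:
        for name in ("percent_identity", "percent_coverage"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValidationError(f"{name}={v} outside [0, 100] for {self.taxon_id!r}")


def read_taxonomy(path) -> list[TaxonomyRecord]:
    df = pd.read_csv(path, sep="\t")
    needed = {"taxon_id", "lineage", "percent_identity", "percent_coverage"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"taxonomy table missing columns: {sorted(missing)}")
    return [
        TaxonomyRecord(
            str(r.taxon_id), str(r.lineage), float(r.percent_identity), float(r.percent_coverage)
        )
        for r in df.itertuples(index=False)
    ]


def write_taxonomy(records: list[TaxonomyRecord], path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, sep="\t", index=False)


def filter_taxonomy(
    records: list[TaxonomyRecord],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list[TaxonomyRecord]:
    """Keep a record's lineage only when identity AND coverage strictly
    exceed their thresholds; everything else becomes "unclassified".

    The output has exactly one record per input record, in input order.
    """
    for name, v in (("min_identity", min_identity), ("min_coverage", min_coverage)):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"{name}={v} outside [0, 100]")
    out = []
    for r in records:
        if r.percent_identity > min_identity and r.percent_coverage > min_coverage:
            out.append(r)
        else:
            out.append(replace(r, lineage="unclassified"))
    return out


# ---------------------------------------------------------------------------
# Dominant-group aggregation and hypoxia flag
# ---------------------------------------------------------------------------


def dominant_taxa(
    table: OTUTable,
    level_map: dict[str, str],
    threshold: float = DEFAULT_DOMINANCE_THRESHOLD,
    samples: list[str] | None = None,
) -> dict[str, float]:
    """Pooled relative abundance per higher-level group (e.g. phylum).

    The table must be relative.  Abundances are averaged over the pooled
    sample set (each sample weighted equally), summed by group, and groups
    whose pooled fraction strictly exceeds ``threshold`` are reported
    individually; the rest are lumped into ``"Others"``.  Taxa absent from
    ``level_map`` fall into an ``"unclassified"`` group (which competes for
    dominance like any other).  Returned fractions sum to 1.
    """
    if not table.is_relative:
        raise ValidationError("dominant_taxa requires a relative table")
    sub = table if samples is None else table.select_samples(samples)
    pooled = sub.counts.mean(axis=1)  # per-taxon pooled fraction, sums to 1
    groups: dict[str, float] = {}
    n_unmapped = 0
    for taxon, frac in zip(sub.taxon_ids, pooled):
        g = level_map.get(taxon)
        if g is None:
            g = "unclassified"
            n_unmapped += 1
        groups[g] = groups.get(g, 0.0) + float(frac)
    if n_unmapped:
        logger.warning("dominant_taxa: %d taxa missing from level_map -> 'unclassified'", n_unmapped)
    out: dict[str, float] = {}
    others = 0.0
    for g in sorted(groups):
        if groups[g] > threshold:
            out[g] = groups[g]
        else:
            others += groups[g]
    if others > 0.0:
        out["Others"] = out.get("Others", 0.0) + others
    return out


def flag_hypoxia(
    meta: SampleMetadata, threshold: float = DEFAULT_HYPOXIA_MG_L, do_column: str = "DO"
) -> dict[str, bool]:
    """Sample -> True when dissolved oxygen is strictly below ``threshold``.

    Samples with a missing DO value are omitted with a warning.
    """
    if do_column not in meta.df.columns:
        raise KeyError(f"metadata has no {do_column!r} column")
    do = pd.to_numeric(meta.df[do_column], errors="coerce")
    out: dict[str, bool] = {}
    for sample, v in do.items():
        if pd.isna(v):
            logger.warning("flag_hypoxia: sample %r has no DO value; omitted", sample)
            continue
        out[str(sample)] = bool(v < threshold)
    return out
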