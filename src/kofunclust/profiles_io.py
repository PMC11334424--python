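"""Readers and writers for every table the pipeline touches.

All tables are delimited text (TSV canonical, CSV accepted by extension),
UTF-8, "." decimal, missing values encoded as empty cells or ``NA``. The
in-memory containers are thin, validated wrappers around numpy arrays and
pandas DataFrames:

* :class:`CountMatrix` — non-negative sample x KO estimated gene-copy counts.
* :class:`SampleTable` — per-sample metadata (ecosystem fields, GC content,
  assembly/annotation statistics, data-use flags).
* :class:`PathwayMap` — KO -> KEGG pathway associations (many-to-many).
* :class:`TaxonomyTable` — per-sample contig counts by taxonomic domain.

Identifiers are treated as opaque strings: KO ids conventionally look like
``K00001`` but no pattern is enforced, so the pipeline can be reused with
other ortholog schemes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "ParseError",
    "CountMatrix",
    "SampleTable",
    "PathwayMap",
    "TaxonomyTable",
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_table",
    "write_sample_table",
    "read_pathway_map",
    "write_pathway_map",
    "read_taxonomy_table",
    "write_taxonomy_table",
]

TAXONOMY_DOMAINS = ("bacteria", "archaea", "eukaryota", "viruses", "unassigned")

#: SampleTable columns with dedicated semantics; anything else is an "extra".
SAMPLE_FIELDS = (
    "ecosystem_type",
    "ecosystem",
    "ecosystem_label",
    "gc_content",
    "gene_count",
    "pct_ko_annotated",
    "has_copy_data",
    "is_combined_assembly",
    "use_restricted",
)


class SchemaError(ValueError):
    """A table violates its structural contract (duplicates, missing columns)."""


class ParseError(ValueError):
    """A cell could not be interpreted (non-numeric or negative count, ...)."""


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise SchemaError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class CountMatrix:
    """Sample x KO estimated gene-copy counts.

    ``values[i, j]`` is the read-coverage-weighted estimated number of gene
    copies annotated with KO ``ko_ids[j]`` in sample ``sample_ids[i]``.
    Values are non-negative finite reals (coverage weighting makes them
    non-integer in general).
    """

    sample_ids: list[str]
    ko_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.ko_ids = [str(k) for k in self.ko_ids]
        self.values = np.asarray(self.values, dtype=float)
        if len(self.sample_ids) < 1 or len(self.ko_ids) < 1:
            raise SchemaError("count matrix needs at least 1 sample and 1 KO")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.ko_ids, "KO")
        if self.values.shape != (len(self.sample_ids), len(self.ko_ids)):
            raise SchemaError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.ko_ids)} KOs"
            )
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ParseError(
                f"non-finite count at sample {self.sample_ids[i]!r}, "
                f"KO {self.ko_ids[j]!r}"
            )
        neg = self.values < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ParseError(
                f"negative count {self.values[i, j]} at sample "
                f"{self.sample_ids[i]!r}, KO {self.ko_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_kos(self) -> int:
        return len(self.ko_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.ko_ids)

    def subset_samples(self, keep: Iterable[str]) -> "CountMatrix":
        keep = list(keep)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in keep]
        return CountMatrix(keep, list(self.ko_ids), self.values[idx])

    def subset_kos(self, keep: Iterable[str]) -> "CountMatrix":
        keep = list(keep)
        pos = {k: j for j, k in enumerate(self.ko_ids)}
        idx = [pos[k] for k in keep]
        return CountMatrix(list(self.sample_ids), keep, self.values[:, idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.ko_ids == other.ko_ids
            and np.array_equal(self.values, other.values)
        )


def read_count_matrix(
    path: str | Path, orientation: str = "samples_as_rows"
) -> CountMatrix:
    """Read a delimited count table; normalize to samples-as-rows.

    ``orientation="samples_as_cols"`` handles the JGI functional-profile
    export convention where KOs are rows and samples are columns.
    """
    if orientation not in ("samples_as_rows", "samples_as_cols"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise SchemaError(f"duplicate row identifier: {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise SchemaError(f"duplicate column identifier: {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric cell {df.iat[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r} of {path}"
        )
    # to_numeric above only *detects* bad cells; astype(float) parses with
    # correct rounding so written matrices round-trip to full precision
    exact = df.astype(float)
    if orientation == "samples_as_cols":
        exact = exact.T
    try:
        return CountMatrix(
            list(exact.index.astype(str)),
            list(exact.columns.astype(str)),
            exact.to_numpy(dtype=float),
        )
    except ParseError as e:
        raise ParseError(f"{e} (file {path})") from e


def write_count_matrix(
    cm: CountMatrix, path: str | Path, orientation: str = "samples_as_rows"
) -> None:
    df = cm.to_frame()
    if orientation == "samples_as_cols":
        df = df.T
    elif orientation != "samples_as_rows":
        raise ValueError(f"unknown orientation: {orientation!r}")
    df.index.name = "id"
    df.to_csv(path, sep=_sep_for(path))


_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False, "t": True, "f": False,
}


def _parse_bool(x: object) -> object:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return pd.NA
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("", "na", "nan"):
        return pd.NA
    if s in _BOOL_MAP:
        return _BOOL_MAP[s]
    raise ParseError(f"cannot interpret {x!r} as a boolean")


@dataclass
class SampleTable:
    """Per-sample metadata keyed by ``sample_id``.

    Backed by a DataFrame indexed by sample_id. Recognized columns get
    typed/validated; unknown columns are preserved untouched as extras.
    Missing optional fields stay missing (NaN / <NA>), never defaulted.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        if df.index.name != "sample_id":
            if "sample_id" not in df.columns:
                raise SchemaError("sample table requires a sample_id column")
            df = df.set_index("sample_id")
        df.index = df.index.astype(str)
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise SchemaError(f"duplicate sample_id: {dup!r}")
        for col in ("gc_content", "pct_ko_annotated", "gene_count"):
            if col in df.columns:
                df[col] = pd.to_numeric(df[col], errors="raise")
        if "gc_content" in df.columns:
            gc = df["gc_content"].dropna()
            out = gc[(gc < 0) | (gc > 1)]
            if len(out):
                raise ValueError(
                    f"gc_content out of [0,1] for sample {out.index[0]!r}: "
                    f"{out.iloc[0]}"
                )
        if "pct_ko_annotated" in df.columns:
            pct = df["pct_ko_annotated"].dropna()
            out = pct[(pct < 0) | (pct > 100)]
            if len(out):
                raise ValueError(
                    f"pct_ko_annotated out of [0,100] for sample "
                    f"{out.index[0]!r}: {out.iloc[0]}"
                )
        for col in ("has_copy_data", "is_combined_assembly", "use_restricted"):
            if col in df.columns:
                df[col] = df[col].map(_parse_bool).astype("boolean")
        self.df = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.df.index

    def column(self, name: str) -> pd.Series:
        """A recognized or extra column; all-missing Series if absent."""
        if name in self.df.columns:
            return self.df[name]
        return pd.Series(pd.NA, index=self.df.index, name=name)

    def with_column(self, name: str, values: pd.Series) -> "SampleTable":
        df = self.df.copy()
        df[name] = values.reindex(df.index)
        return SampleTable(df)

    def subset(self, keep: Iterable[str]) -> "SampleTable":
        return SampleTable(self.df.loc[list(keep)])


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep=_sep_for(path), na_values=["NA", ""], dtype={0: str})
    if "sample_id" not in df.columns:
        raise SchemaError(f"{path}: missing required column sample_id")
    return SampleTable(df)


def write_sample_table(st: SampleTable, path: str | Path) -> None:
    st.df.to_csv(path, sep=_sep_for(path), index=True, index_label="sample_id")


@dataclass
class PathwayMap:
    """KO -> pathway associations; one KO may map to many pathways.

    Entries are ``(ko_id, pathway_id, pathway_name, category)`` with name and
    category possibly ``None``; (ko_id, pathway_id) pairs are unique.
    """

    entries: set = field(default_factory=set)
    n_skipped: int = 0

    def __post_init__(self) -> None:
        pairs = {(k, p) for (k, p, _, _) in self.entries}
        if len(pairs) != len(self.entries):
            # keep first occurrence per (ko, pathway) pair deterministically
            seen: dict[tuple, tuple] = {}
            for e in sorted(self.entries, key=lambda t: tuple(str(x) for x in t)):
                seen.setdefault((e[0], e[1]), e)
            self.entries = set(seen.values())

    def __len__(self) -> int:
        return len(self.entries)

    def pathways_of(self, ko_id: str) -> list[tuple]:
        return sorted(
            (e for e in self.entries if e[0] == ko_id),
            key=lambda t: tuple(str(x) for x in t),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.entries, key=lambda t: tuple(str(x) for x in t))
        return pd.DataFrame(
            rows, columns=["ko_id", "pathway_id", "pathway_name", "category"]
        )


def _strip_prefix(token: str, prefix: str) -> str:
    return token[len(prefix):] if token.startswith(prefix) else token


def read_pathway_map(path: str | Path) -> PathwayMap:
    """Read a KO->pathway map.

    Accepts the canonical 4-column TSV (ko_id, pathway_id, pathway_name,
    category; header optional) and KEGG's 2-column link dialect
    ``ko:Kxxxxx<TAB>path:koNNNNN`` (name/category left missing). Rows with an
    empty or missing ko_id are skipped with a warning and counted.
    """
    entries: set = set()
    n_skipped = 0
    sep = _sep_for(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n\r")
            if not line or line.startswith("#"):
                continue
            parts = line.split(sep)
            if lineno == 1 and parts and parts[0].strip().lower() == "ko_id":
                continue  # header row of the canonical dialect
            ko = _strip_prefix(parts[0].strip(), "ko:")
            if len(parts) < 2 or not ko or not parts[1].strip():
                n_skipped += 1
                logger.warning("%s:%d: malformed pathway-map row skipped", path, lineno)
                continue
            pathway = _strip_prefix(parts[1].strip(), "path:")
            name = parts[2].strip() if len(parts) > 2 and parts[2].strip() not in ("", "NA") else None
            cat = parts[3].strip() if len(parts) > 3 and parts[3].strip() not in ("", "NA") else None
            entries.add((ko, pathway, name, cat))
    if not entries:
        logger.warning("%s: empty pathway map", path)
    return PathwayMap(entries, n_skipped=n_skipped)


def write_pathway_map(pmap: PathwayMap, path: str | Path) -> None:
    df = pmap.to_frame()
    df = df.fillna("NA")
    df.to_csv(path, sep=_sep_for(path), index=False)


@dataclass
class TaxonomyTable:
    """Per-sample contig counts assigned to each taxonomic domain."""

    df: pd.DataFrame  # index sample_id, columns TAXONOMY_DOMAINS, int counts

    def __post_init__(self) -> None:
        df = self.df.copy()
        if df.index.name != "sample_id":
            if "sample_id" not in df.columns:
                raise SchemaError("taxonomy table requires a sample_id column")
            df = df.set_index("sample_id")
        df.index = df.index.astype(str)
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise SchemaError(f"duplicate sample_id: {dup!r}")
        for dom in TAXONOMY_DOMAINS:
            if dom not in df.columns:
                logger.warning("taxonomy table: missing domain %r zero-filled", dom)
                df[dom] = 0
        df = df[list(TAXONOMY_DOMAINS)]
        arr = df.apply(pd.to_numeric, errors="raise").to_numpy()
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise SchemaError(
                f"negative contig count for sample {df.index[i]!r}, "
                f"domain {TAXONOMY_DOMAINS[j]!r}"
            )
        self.df = df.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def counts(self) -> np.ndarray:
        return self.df.to_numpy()


def read_taxonomy_table(path: str | Path) -> TaxonomyTable:
    df = pd.read_csv(path, sep=_sep_for(path), dtype={0: str})
    if "sample_id" not in df.columns:
        raise SchemaError(f"{path}: missing required column sample_id")
    return TaxonomyTable(df)


def write_taxonomy_table(tt: TaxonomyTable, path: str | Path) -> None:
    tt.df.to_csv(path, sep=_sep_for(path), index=True, index_label="sample_id")
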