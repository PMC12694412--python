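"""Domain types and I/O for the viral-phenology pipeline.

The pipeline consumes four external artifacts: a taxa x samples coverage
table (TSV), per-sample metadata (TSV), a phylogeny (newick) and genome
sequences (FASTA, handled in :mod:`viralphenology.hostpred`).  All tabular
output is tab-delimited UTF-8 with a header row and ``NA`` for missing
values; every run writes a JSON manifest recording configuration, seeds and
package versions so results are reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Sample",
    "AbundanceTable",
    "RegularSeries",
    "read_abundance_table",
    "write_abundance_table",
    "read_tree",
    "read_group_map",
    "write_results",
]


@dataclass(frozen=True)
class Sample:
    """One dated metagenomic sample.

    Parameters
    ----------
    sample_id : str
        Unique identifier within a table.
    date : datetime.date
        Collection date; samples are assigned to calendar months by
        (year, month) only — day of month is ignored downstream.
    library_reads : int
        Total sequenced reads in the library; must be positive.  Used to
        normalize trimmed-mean coverage for uneven library sizes.
    fraction : str
        Size-fraction label, e.g. ``"viral"`` (<0.22 um) or ``"cellular"``.
    """

    sample_id: str
    date: _dt.date
    library_reads: int
    fraction: str = "viral"

    def __post_init__(self) -> None:
        if self.library_reads <= 0:
            raise ValueError(
                f"sample {self.sample_id!r}: library_reads must be > 0, "
                f"got {self.library_reads}"
            )

    @property
    def month_index(self) -> int:
        """Absolute month number (year*12 + month-1); grid unit of the pipeline."""
        return self.date.year * 12 + (self.date.month - 1)


@dataclass
class AbundanceTable:
    """Taxa x samples matrix of (trimmed-mean) read-coverage values.

    ``coverage[i, j]`` is the coverage of ``taxa[i]`` in ``samples[j]``.
    Samples are kept sorted by date ascending; entries are nonnegative.
    """

    taxa: list[str]
    samples: list[Sample]
    coverage: np.ndarray

    def __post_init__(self) -> None:
        self.coverage = np.asarray(self.coverage, dtype=float)
        if self.coverage.shape != (len(self.taxa), len(self.samples)):
            raise ValueError(
                f"coverage shape {self.coverage.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.samples)} samples"
            )
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"duplicate taxon ids: {dupes}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        if not np.all(np.isfinite(self.coverage)):
            raise ValueError("coverage contains non-finite values")
        if np.any(self.coverage < 0):
            raise ValueError("coverage contains negative values")
        # keep samples in date order (stable for within-date ties)
        order = sorted(range(len(self.samples)), key=lambda j: (self.samples[j].date, j))
        if order != list(range(len(self.samples))):
            self.samples = [self.samples[j] for j in order]
            self.coverage = self.coverage[:, order]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def dates(self) -> list[_dt.date]:
        return [s.date for s in self.samples]

    @property
    def library_reads(self) -> np.ndarray:
        return np.array([s.library_reads for s in self.samples], dtype=float)

    @property
    def month_indices(self) -> np.ndarray:
        return np.array([s.month_index for s in self.samples], dtype=int)

    def subset_fraction(self, fraction: str) -> "AbundanceTable":
        """Restrict to samples of one size fraction."""
        keep = [j for j, s in enumerate(self.samples) if s.fraction == fraction]
        if not keep:
            raise ValueError(f"no samples with fraction {fraction!r}")
        return AbundanceTable(
            taxa=list(self.taxa),
            samples=[self.samples[j] for j in keep],
            coverage=self.coverage[:, keep].copy(),
        )

    def row(self, taxon_id: str) -> np.ndarray:
        try:
            i = self.taxa.index(taxon_id)
        except ValueError:
            raise KeyError(f"unknown taxon {taxon_id!r}") from None
        return self.coverage[i]


@dataclass
class RegularSeries:
    """One taxon's abundance on a consecutive monthly grid with no gaps.

    ``values[t]`` is the (normalized) abundance in the month ``t`` steps
    after (``start_year``, ``start_month``); ``interpolated_mask[t]`` marks
    months that were filled by linear interpolation rather than observed.
    """

    taxon_id: str
    start_year: int
    start_month: int  # 1..12
    values: np.ndarray
    interpolated_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.interpolated_mask is None:
            self.interpolated_mask = np.zeros(self.values.shape, dtype=bool)
        self.interpolated_mask = np.asarray(self.interpolated_mask, dtype=bool)
        if self.interpolated_mask.shape != self.values.shape:
            raise ValueError("mask length must equal values length")
        if not (1 <= self.start_month <= 12):
            raise ValueError(f"start_month must be in 1..12, got {self.start_month}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("RegularSeries may not contain missing values")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def calendar_months(self) -> np.ndarray:
        """0-based calendar month (0=Jan .. 11=Dec) of each grid point."""
        return (self.start_month - 1 + np.arange(len(self.values))) % 12


def _parse_date(text: str) -> _dt.date:
    try:
        return _dt.date.fromisoformat(str(text).strip())
    except ValueError as exc:
        raise ValueError(f"unparseable ISO-8601 date {text!r}") from exc


def read_abundance_table(path_coverage: str | Path, path_metadata: str | Path) -> AbundanceTable:
    """Read a coverage TSV (taxa rows, sample columns) plus metadata TSV.

    The metadata file must have columns ``sample_id``, ``date`` (ISO-8601),
    ``library_reads`` and ``fraction``; its sample ids must exactly match
    the coverage header.  Samples are returned sorted by date.
    """
    cov = pd.read_csv(path_coverage, sep="\t", index_col=0, na_values=["NA"])
    meta = pd.read_csv(path_metadata, sep="\t", dtype={"sample_id": str}, na_values=["NA"])
    required = {"sample_id", "date", "library_reads", "fraction"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns: {sorted(missing_cols)}")

    cov_ids = [str(c) for c in cov.columns]
    meta_ids = list(meta["sample_id"])
    unknown = sorted(set(meta_ids) - set(cov_ids))
    if unknown:
        raise ValueError(f"metadata sample ids absent from coverage header: {unknown}")
    absent = sorted(set(cov_ids) - set(meta_ids))
    if absent:
        raise ValueError(f"coverage sample ids absent from metadata: {absent}")
    if len(set(meta_ids)) != len(meta_ids):
        raise ValueError("duplicate sample ids in metadata")

    try:
        values = cov.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"coverage contains missing or non-numeric cells: {exc}") from exc
    if np.isnan(values).any():
        raise ValueError("coverage contains missing or non-numeric cells")

    meta = meta.set_index("sample_id").loc[cov_ids]
    samples = [
        Sample(
            sample_id=sid,
            date=_parse_date(row["date"]),
            library_reads=int(row["library_reads"]),
            fraction=str(row["fraction"]),
        )
        for sid, row in meta.iterrows()
    ]
    return AbundanceTable(taxa=[str(t) for t in cov.index], samples=samples, coverage=values)


def write_abundance_table(
    table: AbundanceTable, path_coverage: str | Path, path_metadata: str | Path
) -> None:
    """Write the coverage + metadata TSV pair (inverse of :func:`read_abundance_table`)."""
    cov = pd.DataFrame(table.coverage, index=table.taxa, columns=table.sample_ids)
    cov.index.name = "taxon_id"
    cov.to_csv(path_coverage, sep="\t", float_format="%.10g")
    meta = pd.DataFrame(
        {
            "sample_id": table.sample_ids,
            "date": [d.isoformat() for d in table.dates],
            "library_reads": [s.library_reads for s in table.samples],
            "fraction": [s.fraction for s in table.samples],
        }
    )
    meta.to_csv(path_metadata, sep="\t", index=False)


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a newick tree with branch lengths; duplicate tip labels are an error."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except dendropy.utility.error.DataParseError as exc:
        msg = str(exc)
        if "uplicate" in msg:
            raise ValueError(f"duplicate tip labels: {msg}") from exc
        raise ValueError(f"malformed newick: {msg}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon is not None]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length")
    return tree


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (taxon_id, group); each taxon maps to one group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("group map needs two columns: taxon_id, group")
    taxa = df.iloc[:, 0]
    if taxa.duplicated().any():
        dupes = sorted(taxa[taxa.duplicated()].unique())
        raise ValueError(f"taxon mapped to more than one group: {dupes}")
    return dict(zip(taxa, df.iloc[:, 1]))


def _versions() -> dict[str, str]:
    import scipy

    from viralphenology import __version__

    return {
        "viralphenology": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "dendropy": dendropy.__version__,
    }


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: dict | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write named result tables as deterministic TSVs plus a JSON run manifest.

    Tables are written with a header row, tab delimiter, ``NA`` for missing
    values and ``%.10g`` floats, so identical inputs yield byte-identical
    files.  The manifest records the config, seed and package versions.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, na_rep="NA", float_format="%.10g")
        paths[name] = p
    manifest = {
        "config": _jsonable(config or {}),
        "seed": seed,
        "versions": _versions(),
        "tables": {k: v.name for k, v in paths.items()},
    }
    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = mp
    return paths


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
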