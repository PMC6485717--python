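"""Reading, binning, averaging and normalizing direct-infusion ESI mass spectra.

Spectra are acquired over m/Z 400-2000 at ~0.02 m/Z sampling, collapsed onto
the integer (unit) m/Z grid, and scaled so that the largest 10-m/Z segment
intensity sum equals 1.  Per-sample profiles are replicate-averaged peak-area
vectors stored, together with group labels and covariates, in a cohort table
written as delimited text (TSV by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

MZ_MIN = 400
MZ_MAX = 2000
SEGMENT_WIDTH = 10

#: metadata columns of the peak-table format, in on-disk order
_META_COLS = ("sample_id", "group", "age")
_COVARIATE_PREFIX = "covariate:"


class DegenerateAnalysisError(ValueError):
    """An analysis step produced no usable output (e.g. no significant peaks)."""


def mz_grid(mz_min: int = MZ_MIN, mz_max: int = MZ_MAX) -> np.ndarray:
    """Integer m/Z grid, inclusive of both endpoints."""
    return np.arange(mz_min, mz_max + 1)


# ---------------------------------------------------------------------------
# raw spectra
# ---------------------------------------------------------------------------

@dataclass
class RawSpectrum:
    """A centroided spectrum: parallel (m/Z, intensity) arrays for one acquisition."""

    mz: np.ndarray
    intensity: np.ndarray
    acquisition_id: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity in raw spectrum")
        if np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (not banker's rounding)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def bin_to_unit_mz(
    raw: RawSpectrum | tuple[np.ndarray, np.ndarray],
    mz_min: int = MZ_MIN,
    mz_max: int = MZ_MAX,
) -> np.ndarray:
    """Collapse a raw spectrum onto the unit m/Z grid.

    Each point's intensity is added to the bin at ``round(mz)`` (half away
    from zero); points whose rounded m/Z falls outside ``[mz_min, mz_max]``
    are dropped.  Returns an intensity vector aligned to
    ``mz_grid(mz_min, mz_max)``.
    """
    if not isinstance(raw, RawSpectrum):
        raw = RawSpectrum(*raw)
    idx = round_half_away(raw.mz).astype(np.int64) - mz_min
    n_bins = mz_max - mz_min + 1
    keep = (idx >= 0) & (idx < n_bins)
    return np.bincount(idx[keep], weights=raw.intensity[keep], minlength=n_bins)


def binned_from_dict(
    d: Mapping[int, float], mz_min: int = MZ_MIN, mz_max: int = MZ_MAX
) -> np.ndarray:
    """Build a grid-aligned intensity vector from a sparse {m/Z: intensity} map."""
    out = np.zeros(mz_max - mz_min + 1)
    for mz, v in d.items():
        if not mz_min <= mz <= mz_max:
            raise ValueError(f"m/Z {mz} outside grid [{mz_min}, {mz_max}]")
        if v < 0:
            raise ValueError("negative intensity")
        out[int(mz) - mz_min] = v
    return out


def average_replicates(replicates: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise mean over replicate binned spectra (missing bins count as 0)."""
    if len(replicates) == 0:
        raise ValueError("need at least one replicate spectrum")
    stack = np.asarray(replicates, dtype=float)
    if stack.ndim != 2:
        raise ValueError("replicates must share one m/Z grid")
    return stack.mean(axis=0)


def segment_sums(
    binned: np.ndarray, segment_width: int = SEGMENT_WIDTH
) -> tuple[np.ndarray, np.ndarray]:
    """Intensity sum of each consecutive ``segment_width``-m/Z segment.

    With the default grid this yields 160 segments [400,410), ... [1990,2000];
    the final segment absorbs the closing grid point.  Returns
    ``(start_offsets, sums)``.
    """
    binned = np.asarray(binned, dtype=float)
    n = binned.size
    starts = np.arange(0, n - 1, segment_width)
    return starts, np.add.reduceat(binned, starts)


def normalize_segments(
    binned: np.ndarray,
    segment_width: int = SEGMENT_WIDTH,
    mode: str = "global",
) -> np.ndarray:
    """Scale a binned spectrum by its 10-m/Z segment intensity sums.

    mode="global" (default): one scalar — every intensity is divided by the
    maximum segment sum, so the largest segment sums to exactly 1 afterwards.
    mode="per-segment": each segment is divided by its own sum (all-zero
    segments stay zero).
    """
    binned = np.asarray(binned, dtype=float)
    if np.any(binned < 0):
        raise ValueError("negative intensity")
    starts, sums = segment_sums(binned, segment_width)
    if not np.any(sums > 0):
        raise DegenerateAnalysisError("all-zero spectrum cannot be normalized")
    if mode == "global":
        return binned / sums.max()
    if mode == "per-segment":
        out = binned.copy()
        bounds = np.append(starts, binned.size)
        for lo, hi, s in zip(bounds[:-1], bounds[1:], sums):
            if s > 0:
                out[lo:hi] /= s
        return out
    raise ValueError(f"unknown normalization mode {mode!r}")


# ---------------------------------------------------------------------------
# sample profiles and cohort tables
# ---------------------------------------------------------------------------

@dataclass
class SampleProfile:
    """One subject's replicate-averaged, normalized peak areas with metadata."""

    sample_id: str
    group: str
    areas: pd.Series  # index: integer m/Z
    age: float | None = None
    covariates: dict[str, float] = field(default_factory=dict)


@dataclass
class CohortTable:
    """Cohort of sample profiles: metadata frame + (samples x m/Z) area matrix."""

    samples: pd.DataFrame  # index sample_id; columns group, age, covariate:*
    areas: pd.DataFrame    # index sample_id; columns integer m/Z, ascending

    def __post_init__(self) -> None:
        if self.samples.index.has_duplicates:
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise ValueError(f"duplicate sample_id {dup!r}")
        if not self.samples.index.equals(self.areas.index):
            raise ValueError("samples and areas must share the same sample_id index")
        cols = np.asarray(self.areas.columns, dtype=np.int64)
        if cols.size and not np.array_equal(cols, np.arange(cols[0], cols[-1] + 1)):
            raise ValueError("area columns must be a contiguous integer m/Z grid")
        self.areas.columns = cols
        if (self.areas.to_numpy() < 0).any():
            raise ValueError("negative peak area")

    # -- introspection -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def group_labels(self) -> list[str]:
        return sorted(self.samples["group"].dropna().unique())

    def group_sizes(self) -> dict[str, int]:
        return self.samples["group"].value_counts().to_dict()

    def require_binary(self) -> tuple[str, str]:
        """Validate the two-group invariant; returns the labels, sorted."""
        labels = self.group_labels
        if len(labels) != 2:
            raise ValueError(f"binary analysis requires exactly 2 groups, got {labels}")
        sizes = self.group_sizes()
        for g in labels:
            if sizes.get(g, 0) < 2:
                raise ValueError(f"group {g!r} has fewer than 2 samples")
        return labels[0], labels[1]

    # -- access ------------------------------------------------------------
    def profile(self, sample_id: str) -> SampleProfile:
        row = self.samples.loc[sample_id]
        covs = {
            c[len(_COVARIATE_PREFIX):]: row[c]
            for c in self.samples.columns
            if c.startswith(_COVARIATE_PREFIX)
        }
        age = row.get("age")
        return SampleProfile(
            sample_id=sample_id,
            group=row["group"],
            areas=self.areas.loc[sample_id],
            age=None if pd.isna(age) else float(age),
            covariates=covs,
        )

    def profiles(self) -> Iterator[SampleProfile]:
        for sid in self.samples.index:
            yield self.profile(sid)

    def subset(self, sample_ids: Iterable[str]) -> "CohortTable":
        ids = list(sample_ids)
        return CohortTable(self.samples.loc[ids].copy(), self.areas.loc[ids].copy())

    def with_groups(self, new_groups: Sequence[str]) -> "CohortTable":
        samples = self.samples.copy()
        samples["group"] = list(new_groups)
        return CohortTable(samples, self.areas.copy())


def cohort_from_profiles(profiles: Sequence[SampleProfile]) -> CohortTable:
    if not profiles:
        raise ValueError("empty profile sequence")
    meta = {}
    for p in profiles:
        row: dict[str, object] = {"group": p.group, "age": p.age}
        row.update({_COVARIATE_PREFIX + k: v for k, v in p.covariates.items()})
        meta[p.sample_id] = row
    samples = pd.DataFrame.from_dict(meta, orient="index")
    samples.index.name = "sample_id"
    areas = pd.DataFrame(
        {p.sample_id: p.areas for p in profiles}
    ).T.reindex(samples.index)
    return CohortTable(samples, areas)


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def read_raw_spectrum(path: str | Path, sample_id: str = "") -> RawSpectrum:
    """Read a two-column (m/Z, intensity) delimited text export."""
    path = Path(path)
    frame = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (m/Z, intensity)")
    # tolerate an optional header row
    try:
        float(frame.iat[0, 0])
    except (TypeError, ValueError):
        frame = frame.iloc[1:]
    mz = pd.to_numeric(frame.iloc[:, 0], errors="raise").to_numpy()
    inten = pd.to_numeric(frame.iloc[:, 1], errors="raise").to_numpy()
    return RawSpectrum(mz, inten, acquisition_id=path.stem, sample_id=sample_id or path.stem)


def read_mzml(path: str | Path, sample_id: str = "") -> list[RawSpectrum]:
    """Read all centroided spectra from an mzML file."""
    from pyteomics import mzml  # deferred: only needed for mzML input

    out = []
    with mzml.read(str(path)) as reader:
        for i, spec in enumerate(reader):
            out.append(
                RawSpectrum(
                    spec["m/z array"],
                    spec["intensity array"],
                    acquisition_id=spec.get("id", f"scan={i}"),
                    sample_id=sample_id or Path(path).stem,
                )
            )
    return out


def read_peak_table(
    path: str | Path,
    sep: str | None = None,
    mz_min: int = MZ_MIN,
    mz_max: int = MZ_MAX,
) -> CohortTable:
    """Read a cohort peak table (samples x integer m/Z) from delimited text.

    Layout: ``sample_id, group, age, covariate:*`` metadata columns followed by
    integer m/Z columns.  m/Z columns missing inside ``[mz_min, mz_max]`` are
    filled with 0 (with a warning); duplicate sample ids are an error.
    """
    frame = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if "sample_id" not in frame.columns or "group" not in frame.columns:
        raise ValueError(f"{path}: peak table needs 'sample_id' and 'group' columns")
    dup = frame["sample_id"][frame["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample_id {dup.iloc[0]!r} in {path}")

    mz_cols: dict[int, str] = {}
    for c in frame.columns:
        try:
            mz_cols[int(str(c))] = c
        except ValueError:
            continue
    meta_cols = [c for c in frame.columns if c not in mz_cols.values()]
    known = set(_META_COLS)
    for c in meta_cols:
        if c not in known and not c.startswith(_COVARIATE_PREFIX):
            raise ValueError(f"unrecognized metadata column {c!r} (row 1, column {c!r})")

    grid = mz_grid(mz_min, mz_max)
    missing = [m for m in grid if m not in mz_cols]
    if missing:
        warnings.warn(
            f"{len(missing)} m/Z columns missing in [{mz_min}, {mz_max}]; filled with 0",
            stacklevel=2,
        )
    samples = frame.set_index("sample_id")[
        [c for c in meta_cols if c != "sample_id"]
    ]
    if "age" not in samples.columns:
        samples["age"] = np.nan
    areas = pd.DataFrame(0.0, index=samples.index, columns=grid)
    for m in grid:
        if m in mz_cols:
            col = pd.to_numeric(frame[mz_cols[m]], errors="coerce")
            bad = col.isna() & frame[mz_cols[m]].notna()
            if bad.any():
                r = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"unparseable value at row {r + 2}, column {mz_cols[m]!r}"
                )
            areas[m] = col.fillna(0.0).to_numpy()
    return CohortTable(samples, areas)


def write_peak_table(table: CohortTable, path: str | Path, sep: str = "\t") -> None:
    """Write a cohort table in the delimited layout read by :func:`read_peak_table`."""
    meta = table.samples.copy()
    ordered = [c for c in _META_COLS[1:] if c in meta.columns]
    ordered += sorted(c for c in meta.columns if c.startswith(_COVARIATE_PREFIX))
    out = pd.concat([meta[ordered], table.areas], axis=1)
    out.index.name = "sample_id"
    out.to_csv(path, sep=sep)
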