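"""Core domain types and file I/O.

Holds the four containers the rest of the package operates on —
multilocus genotype tables, spatial detection histories, binary cover
rasters, and the discretized SCR state space (habitat mask) — together
with readers/writers for the plain-text formats used in the field
(delimited genotype tables, GENEPOP, secr-style capture/trap files,
ESRI ASCII grids).

All coordinates are assumed to be in a planar metric CRS; the internal
unit is kilometres and distances are Euclidean.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: allele code used for a missing call
MISSING = 0


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be interpreted."""


class DetectionParseError(ValueError):
    """Raised when capture/trap files cannot be interpreted."""


# ---------------------------------------------------------------------------
# Genotype table
# ---------------------------------------------------------------------------


@dataclass
class GenotypeTable:
    """Diploid multilocus genotypes for one or more sampling periods.

    Parameters
    ----------
    individual_id
        Unique labels (unique within period).
    sex
        Per individual, one of ``"M"``, ``"F"``, ``"unknown"``.
    period
        Sampling-period label per individual (e.g. ``"2010-2012"``).
    loci
        Ordered locus names, identical for every individual.
    calls
        Integer array of shape ``(n_individuals, n_loci, 2)``; allele
        codes are positive integers, ``0`` marks a missing call.  A
        locus is *usable* for an individual only when both alleles are
        non-missing.
    """

    individual_id: list[str]
    sex: list[str]
    period: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=int)
        n, L = len(self.individual_id), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)"
            )
        if (self.calls < 0).any():
            raise ValueError("allele codes must be non-negative integers")
        # both-or-neither missing per pair
        miss = self.calls == MISSING
        bad = miss[..., 0] != miss[..., 1]
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"half-missing allele pair for individual "
                f"{self.individual_id[i]!r} at locus {self.loci[j]!r}"
            )
        for per in set(self.period):
            ids = [i for i, p in zip(self.individual_id, self.period) if p == per]
            if len(ids) != len(set(ids)):
                dup = sorted({i for i in ids if ids.count(i) > 1})
                raise ValueError(
                    f"duplicate individual_id within period {per!r}: {dup}"
                )

    @property
    def n_individuals(self) -> int:
        return len(self.individual_id)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def usable(self) -> np.ndarray:
        """Boolean (n, L): both alleles called."""
        return (self.calls != MISSING).all(axis=2)

    def periods(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.period:
            seen.setdefault(p, None)
        return list(seen)

    def subset(self, rows: Sequence[int] | np.ndarray) -> "GenotypeTable":
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return GenotypeTable(
            [self.individual_id[i] for i in rows],
            [self.sex[i] for i in rows],
            [self.period[i] for i in rows],
            list(self.loci),
            self.calls[rows],
        )

    def for_period(self, period: str) -> "GenotypeTable":
        return self.subset([i for i, p in enumerate(self.period) if p == period])


_PAIR_RE = re.compile(r"[/|,:]")


def _parse_pair(cell: object, individual: str, locus: str) -> tuple[int, int]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return (MISSING, MISSING)
    parts = [p for p in _PAIR_RE.split(str(cell).strip()) if p != ""]
    if len(parts) != 2:
        raise GenotypeParseError(
            f"expected 2 alleles for individual {individual!r} at locus "
            f"{locus!r}, got {len(parts)}: {cell!r}"
        )
    try:
        a, b = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise GenotypeParseError(
            f"non-integer allele for individual {individual!r} at locus "
            f"{locus!r}: {cell!r}"
        ) from exc
    if (a == MISSING) != (b == MISSING):
        raise GenotypeParseError(
            f"half-missing pair for individual {individual!r} at locus "
            f"{locus!r}: {cell!r}"
        )
    return (a, b)


def read_genotype_table(
    source,
    *,
    id_col: str = "individual_id",
    sex_col: str | None = "sex",
    period_col: str | None = "period",
    loci: Sequence[str] | None = None,
    sep: str | None = None,
    default_period: str = "all",
) -> GenotypeTable:
    """Read a delimited genotype table.

    The header declares the loci: either one column per locus holding a
    delimited pair (``"120/124"``) or two columns per locus named
    ``<locus>_1`` / ``<locus>_2``.  ``0`` encodes a missing allele; both
    alleles of a pair must be missing together.

    ``loci`` restricts/orders the locus set; by default every non-ID
    column is treated as a locus.  ``sep=None`` sniffs comma vs
    whitespace.
    """
    df = pd.read_csv(source, sep=sep, engine="python", dtype=str)
    df.columns = [str(c).strip() for c in df.columns]
    if id_col not in df.columns:
        raise GenotypeParseError(f"missing id column {id_col!r}")

    meta_cols = {id_col}
    if sex_col and sex_col in df.columns:
        meta_cols.add(sex_col)
    if period_col and period_col in df.columns:
        meta_cols.add(period_col)

    cols = [c for c in df.columns if c not in meta_cols]
    paired: dict[str, tuple[str, str]] = {}
    singles: list[str] = []
    for c in cols:
        m = re.fullmatch(r"(.+)[._]([12])", c)
        if m and m.group(2) == "1":
            other = None
            for suffix in ("_2", ".2"):
                if m.group(1) + suffix in cols:
                    other = m.group(1) + suffix
            if other is not None:
                paired[m.group(1)] = (c, other)
                continue
        if m and m.group(2) == "2" and m.group(1) in paired:
            continue
        singles.append(c)

    locus_names = list(paired) + [s for s in singles if s not in paired]
    if loci is not None:
        missing = [l for l in loci if l not in locus_names]
        if missing:
            raise GenotypeParseError(f"loci not found in header: {missing}")
        locus_names = list(loci)

    ids = df[id_col].astype(str).tolist()
    sexes = (
        df[sex_col].fillna("unknown").astype(str).tolist()
        if sex_col and sex_col in df.columns
        else ["unknown"] * len(df)
    )
    periods = (
        df[period_col].astype(str).tolist()
        if period_col and period_col in df.columns
        else [default_period] * len(df)
    )

    calls = np.zeros((len(df), len(locus_names), 2), dtype=int)
    for j, locus in enumerate(locus_names):
        if locus in paired:
            c1, c2 = paired[locus]
            for i in range(len(df)):
                a = df[c1].iloc[i]
                b = df[c2].iloc[i]
                a = MISSING if pd.isna(a) else int(a)
                b = MISSING if pd.isna(b) else int(b)
                if (a == MISSING) != (b == MISSING):
                    raise GenotypeParseError(
                        f"half-missing pair for individual {ids[i]!r} at "
                        f"locus {locus!r} (row {i})"
                    )
                calls[i, j] = (a, b)
        else:
            for i in range(len(df)):
                calls[i, j] = _parse_pair(df[locus].iloc[i], ids[i], locus)

    n_missing = int(((calls == MISSING).all(axis=2)).sum())
    if n_missing:
        logger.info("read_genotype_table: %d missing locus calls", n_missing)
    return GenotypeTable(ids, sexes, periods, locus_names, calls)


def write_genotype_table(gt: GenotypeTable, path) -> None:
    """Write the delimited form read by :func:`read_genotype_table`."""
    rows = []
    for i, ind in enumerate(gt.individual_id):
        row = {"individual_id": ind, "sex": gt.sex[i], "period": gt.period[i]}
        for j, locus in enumerate(gt.loci):
            row[locus] = f"{gt.calls[i, j, 0]}/{gt.calls[i, j, 1]}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GENEPOP
# ---------------------------------------------------------------------------


def read_genepop(source) -> GenotypeTable:
    """Read a GENEPOP file (2- or 3-digit allele coding).

    Each ``POP`` block becomes a period labelled ``pop1``, ``pop2``, ...
    unless the first sample id in the block carries a ``period=`` tag.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    lines = [l.rstrip("\n") for l in text.splitlines() if l.strip() != ""]
    if len(lines) < 3:
        raise GenotypeParseError("GENEPOP file too short")
    # title line, then locus names until first POP
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        # loci may be comma-separated on one line
        loci.extend([t.strip() for t in lines[i].split(",") if t.strip()])
        i += 1
    if i == len(lines):
        raise GenotypeParseError("no POP keyword found")

    ids: list[str] = []
    sexes: list[str] = []
    periods: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    width: int | None = None
    pop_idx = 0
    while i < len(lines):
        if lines[i].strip().upper() == "POP":
            pop_idx += 1
            i += 1
            continue
        line = lines[i]
        if "," not in line:
            raise GenotypeParseError(f"missing comma in sample line: {line!r}")
        name, genostr = line.split(",", 1)
        tokens = genostr.split()
        if len(tokens) != len(loci):
            raise GenotypeParseError(
                f"sample {name.strip()!r}: {len(tokens)} genotypes for "
                f"{len(loci)} loci"
            )
        pairs: list[tuple[int, int]] = []
        for tok, locus in zip(tokens, loci):
            if len(tok) not in (4, 6):
                raise GenotypeParseError(
                    f"bad genotype width {tok!r} at locus {locus!r}"
                )
            w = len(tok) // 2
            if width is None:
                width = w
            elif w != width:
                raise GenotypeParseError(
                    f"inconsistent allele-code width at locus {locus!r}: "
                    f"{tok!r} (expected {2 * width} digits)"
                )
            pairs.append((int(tok[:w]), int(tok[w:])))
        ids.append(name.strip())
        sexes.append("unknown")
        periods.append(f"pop{pop_idx}")
        rows.append(pairs)
        i += 1

    calls = np.array(rows, dtype=int) if rows else np.zeros((0, len(loci), 2), int)
    return GenotypeTable(ids, sexes, periods, loci, calls)


def write_genepop(gt: GenotypeTable, path=None, *, title: str = "fragpop export") -> str:
    """Write GENEPOP text (one POP block per period); returns the text."""
    width = 3 if int(gt.calls.max(initial=0)) > 99 else 2
    out = io.StringIO()
    out.write(title + "\n")
    for locus in gt.loci:
        out.write(locus + "\n")
    for per in gt.periods():
        out.write("POP\n")
        sub = gt.for_period(per)
        for i, ind in enumerate(sub.individual_id):
            toks = [
                f"{sub.calls[i, j, 0]:0{width}d}{sub.calls[i, j, 1]:0{width}d}"
                for j in range(sub.n_loci)
            ]
            out.write(f"{ind}, " + " ".join(toks) + "\n")
    text = out.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Detection histories
# ---------------------------------------------------------------------------


@dataclass
class DetectionData:
    """Binary proximity-detector capture histories over one or more sessions.

    ``y[session]`` is a ``(n_detected, n_traps, n_occasions)`` 0/1 array
    whose rows correspond to ``individuals[session]``; an individual may
    appear in several sessions.  ``traps[session]`` is a DataFrame with
    columns ``trap_id, x, y`` (km).
    """

    sessions: list[str]
    traps: dict[str, pd.DataFrame]
    n_occasions: dict[str, int]
    y: dict[str, np.ndarray]
    individuals: dict[str, list[str]]
    sex: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.sessions:
            arr = np.asarray(self.y[s], dtype=int)
            if not np.isin(arr, [0, 1]).all():
                raise ValueError("detection tensor must be binary")
            J = len(self.traps[s])
            K = self.n_occasions[s]
            n = len(self.individuals[s])
            if arr.shape != (n, J, K):
                raise ValueError(
                    f"session {s}: y shape {arr.shape} != ({n}, {J}, {K})"
                )
            self.y[s] = arr
            xy = self.traps[s][["x", "y"]].to_numpy(float)
            if not np.isfinite(xy).all():
                raise ValueError(f"session {s}: non-finite trap coordinates")

    def all_individuals(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sessions:
            for ind in self.individuals[s]:
                seen.setdefault(ind, None)
        return list(seen)

    def n_histories(self) -> int:
        """Total detected individuals summed over sessions (AICc sample size)."""
        return sum(len(self.individuals[s]) for s in self.sessions)

    def filter_sex(self, sex: str) -> "DetectionData":
        keep_y, keep_ind = {}, {}
        for s in self.sessions:
            idx = [
                i
                for i, ind in enumerate(self.individuals[s])
                if self.sex.get(ind) == sex
            ]
            keep_ind[s] = [self.individuals[s][i] for i in idx]
            keep_y[s] = self.y[s][idx]
        return DetectionData(
            list(self.sessions),
            dict(self.traps),
            dict(self.n_occasions),
            keep_y,
            keep_ind,
            {k: v for k, v in self.sex.items() if v == sex},
        )


def read_detections(
    capture_source,
    trap_source,
    *,
    n_occasions: int | Mapping[str, int] | None = None,
    capture_cols: Sequence[str] = ("session", "individual", "occasion", "trap_id"),
    sex_col: str | None = "sex",
    sep: str | None = None,
) -> DetectionData:
    """Read secr-style capture and trap-layout text files.

    ``capture_source`` rows: session, individual, occasion, trap_id
    (+ optional sex column).  ``trap_source`` rows: trap_id, x, y with an
    optional ``session`` column (layouts may differ between sessions, as
    when traps are moved between years).  Repeated identical detection
    rows collapse to a single binary entry (proximity data).
    """
    cap = pd.read_csv(capture_source, sep=sep, engine="python", dtype=str)
    cap.columns = [c.strip() for c in cap.columns]
    for c in capture_cols:
        if c not in cap.columns:
            raise DetectionParseError(f"capture file missing column {c!r}")
    trp = pd.read_csv(trap_source, sep=sep, engine="python")
    trp.columns = [str(c).strip() for c in trp.columns]
    for c in ("trap_id", "x", "y"):
        if c not in trp.columns:
            raise DetectionParseError(f"trap file missing column {c!r}")
    trp["trap_id"] = trp["trap_id"].astype(str)

    sess_col, ind_col, occ_col, trap_col = capture_cols
    sessions = list(dict.fromkeys(cap[sess_col].astype(str)))

    traps: dict[str, pd.DataFrame] = {}
    for s in sessions:
        if "session" in trp.columns:
            t = trp[trp["session"].astype(str) == s]
            if t.empty:
                raise DetectionParseError(f"no traps for session {s!r}")
        else:
            t = trp
        t = t[["trap_id", "x", "y"]].reset_index(drop=True)
        if t["trap_id"].duplicated().any():
            raise DetectionParseError(f"duplicate trap_id in session {s!r}")
        traps[s] = t

    occ: dict[str, int] = {}
    for s in sessions:
        rows = cap[cap[sess_col].astype(str) == s]
        k_max = rows[occ_col].astype(int).max()
        if n_occasions is None:
            occ[s] = int(k_max)
        elif isinstance(n_occasions, Mapping):
            occ[s] = int(n_occasions[s])
        else:
            occ[s] = int(n_occasions)

    y: dict[str, np.ndarray] = {}
    individuals: dict[str, list[str]] = {}
    sex: dict[str, str] = {}
    for s in sessions:
        rows = cap[cap[sess_col].astype(str) == s]
        inds = list(dict.fromkeys(rows[ind_col].astype(str)))
        trap_index = {t: j for j, t in enumerate(traps[s]["trap_id"])}
        arr = np.zeros((len(inds), len(trap_index), occ[s]), dtype=int)
        ind_index = {ind: i for i, ind in enumerate(inds)}
        for _, r in rows.iterrows():
            tid = str(r[trap_col])
            if tid not in trap_index:
                raise DetectionParseError(
                    f"unknown trap_id {tid!r} in session {s!r}"
                )
            k = int(r[occ_col])
            if not 1 <= k <= occ[s]:
                raise DetectionParseError(
                    f"occasion {k} outside 1..{occ[s]} in session {s!r}"
                )
            arr[ind_index[str(r[ind_col])], trap_index[tid], k - 1] = 1
            if sex_col and sex_col in cap.columns and not pd.isna(r[sex_col]):
                sex[str(r[ind_col])] = str(r[sex_col])
        y[s] = arr
        individuals[s] = inds

    return DetectionData(sessions, traps, occ, y, individuals, sex)


def write_detections(data: DetectionData, capture_path, trap_path) -> None:
    """Write the secr-style text files read by :func:`read_detections`."""
    cap_rows = []
    for s in data.sessions:
        tids = data.traps[s]["trap_id"].tolist()
        idx = np.argwhere(data.y[s] == 1)
        for i, j, k in idx:
            row = {
                "session": s,
                "individual": data.individuals[s][i],
                "occasion": k + 1,
                "trap_id": tids[j],
            }
            sx = data.sex.get(data.individuals[s][i])
            if sx:
                row["sex"] = sx
            cap_rows.append(row)
    pd.DataFrame(cap_rows).to_csv(capture_path, index=False)
    trap_rows = []
    for s in data.sessions:
        t = data.traps[s].copy()
        t.insert(0, "session", s)
        trap_rows.append(t)
    pd.concat(trap_rows).to_csv(trap_path, index=False)


# ---------------------------------------------------------------------------
# Cover raster
# ---------------------------------------------------------------------------

NODATA = -1


@dataclass
class CoverRaster:
    """Regular binary natural/non-natural cover grid.

    ``values[0, 0]`` is the **top-left** (north-west) cell, following
    raster-file convention; ``(x0, y0)`` is the lower-left corner of the
    grid and ``cell_size`` its resolution, both in the declared unit.
    Values are ``1`` (natural), ``0`` (non-natural) or ``-1`` (nodata).
    """

    values: np.ndarray
    x0: float = 0.0
    y0: float = 0.0
    cell_size: float = 1.0
    unit: str = "km"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not np.isin(self.values, [0, 1, NODATA]).all():
            raise ValueError("cover values limited to {0, 1, nodata}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinate grids matching ``values`` layout."""
        xs = self.x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y0 + (self.n_rows - np.arange(self.n_rows) - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def value_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Cover value of the cell containing each (x, y); nodata outside."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row = self.n_rows - 1 - np.floor((y - self.y0) / self.cell_size).astype(int)
        ok = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        out = np.full(x.shape, NODATA, dtype=int)
        out[ok] = self.values[row[ok], col[ok]]
        return out


def read_esri_ascii(source, unit: str = "km") -> CoverRaster:
    """Read an ESRI ASCII grid (.asc) into a :class:`CoverRaster`."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ESRI ASCII header missing {key}")
    vals = np.loadtxt(io.StringIO("\n".join(lines[i:])))
    vals = np.atleast_2d(vals)
    if vals.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ESRI ASCII data shape does not match header")
    nodata = header.get("nodata_value")
    out = vals.astype(int)
    if nodata is not None:
        out[vals == nodata] = NODATA
    return CoverRaster(
        out, header["xllcorner"], header["yllcorner"], header["cellsize"], unit
    )


def write_esri_ascii(raster: CoverRaster, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {raster.x0}\n")
        fh.write(f"yllcorner {raster.y0}\n")
        fh.write(f"cellsize {raster.cell_size}\n")
        fh.write(f"NODATA_value {NODATA}\n")
        np.savetxt(fh, raster.values, fmt="%d")


def reclassify_cover(
    values: np.ndarray | CoverRaster,
    natural_classes: Iterable[int],
    *,
    nodata: int = NODATA,
    x0: float = 0.0,
    y0: float = 0.0,
    cell_size: float = 1.0,
    unit: str = "km",
) -> CoverRaster:
    """Reclassify a categorical land-cover grid into binary natural cover.

    Cells whose class code is in ``natural_classes`` become 1, all other
    data cells 0; nodata is preserved.  Idempotent when applied to an
    already-binary raster with ``natural_classes={1}``.
    """
    natural = set(int(c) for c in natural_classes)
    if not natural:
        raise ValueError("natural_classes must not be empty")
    if isinstance(values, CoverRaster):
        x0, y0, cell_size, unit = values.x0, values.y0, values.cell_size, values.unit
        arr = values.values
    else:
        arr = np.asarray(values, dtype=int)
    out = np.where(np.isin(arr, list(natural)), 1, 0)
    out[arr == nodata] = NODATA
    if (arr == nodata).all():
        logger.warning("reclassify_cover: raster is entirely nodata")
    return CoverRaster(out, x0, y0, cell_size, unit)


# ---------------------------------------------------------------------------
# Habitat mask (SCR state space)
# ---------------------------------------------------------------------------


@dataclass
class HabitatMask:
    """Discretized state space for SCR activity-center integration."""

    points: np.ndarray  # (n, 2) cell centers, km
    spacing: float  # km
    habitat_flag: np.ndarray | None = None
    covariates: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("mask points must be (n, 2)")
        if self.habitat_flag is not None:
            self.habitat_flag = np.asarray(self.habitat_flag, bool)
            if self.habitat_flag.shape[0] != len(self.points):
                raise ValueError("habitat_flag length mismatch")
        for name, v in self.covariates.items():
            v = np.asarray(v, float)
            if not np.isfinite(v).all():
                raise ValueError(f"covariate {name!r} has non-finite values")
            self.covariates[name] = v

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def cell_area(self) -> float:
        """km² per mask cell (= spacing²)."""
        return self.spacing**2

    @property
    def total_area(self) -> float:
        return self.n_points * self.cell_area

    def habitat_area(self) -> float:
        """km² of mask cells flagged as habitat (all cells if unflagged)."""
        if self.habitat_flag is None:
            return self.total_area
        return float(self.habitat_flag.sum()) * self.cell_area


def build_mask(
    traps: pd.DataFrame | np.ndarray,
    buffer: float,
    spacing: float,
    cover: CoverRaster | None = None,
    pnat: np.ndarray | None = None,
    clip_to_cover: bool = False,
) -> HabitatMask:
    """Build the SCR state space by buffering trap locations.

    Lattice points with ``spacing`` km separation (anchored on the trap
    bounding box) that lie within Euclidean distance ``buffer`` of any
    trap are retained.  When ``cover`` is given, each point gets
    ``habitat_flag`` = natural cover of the containing raster cell, and,
    when ``pnat`` (a fractional grid aligned with ``cover``) is given, a
    ``pnat`` covariate in [0, 1].
    """
    if buffer <= 0 or spacing <= 0:
        raise ValueError("buffer and spacing must be positive")
    if isinstance(traps, pd.DataFrame):
        xy = traps[["x", "y"]].to_numpy(float)
    else:
        xy = np.asarray(traps, float).reshape(-1, 2)
    if len(xy) == 0:
        raise ValueError("no traps supplied")

    xmin, ymin = xy.min(axis=0) - buffer
    xmax, ymax = xy.max(axis=0) + buffer
    xs = xy[:, 0].min() + np.arange(
        -np.ceil(buffer / spacing), np.ceil((xmax - xy[:, 0].min()) / spacing) + 1
    ) * spacing
    ys = xy[:, 1].min() + np.arange(
        -np.ceil(buffer / spacing), np.ceil((ymax - xy[:, 1].min()) / spacing) + 1
    ) * spacing
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    d2 = ((pts[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    keep = (d2.min(axis=1) <= buffer**2 + 1e-9)
    pts = pts[keep]

    habitat = None
    covs: dict[str, np.ndarray] = {}
    if cover is not None:
        vals = cover.value_at(pts[:, 0], pts[:, 1])
        uncovered = np.flatnonzero(vals == NODATA)
        if uncovered.size and clip_to_cover:
            pts = pts[vals != NODATA]
            vals = vals[vals != NODATA]
        elif uncovered.size:
            raise ValueError(
                f"cover raster does not cover {uncovered.size} mask points, "
                f"e.g. {pts[uncovered[:3]].tolist()}"
            )
        habitat = vals == 1
        if pnat is not None:
            # same cell-index arithmetic as value_at, on the aligned grid
            x = pts[:, 0]
            y = pts[:, 1]
            col = np.floor((x - cover.x0) / cover.cell_size).astype(int)
            row = cover.n_rows - 1 - np.floor(
                (y - cover.y0) / cover.cell_size
            ).astype(int)
            covs["pnat"] = np.asarray(pnat, float)[row, col]

    return HabitatMask(pts, spacing, habitat, covs)
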