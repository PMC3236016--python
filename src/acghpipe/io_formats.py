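"""Readers and writers for the pipeline's tabular formats.

Formats handled here:

* clone map — BED-like TSV (``chrom  start  end  clone_id``), 0-based
  half-open on disk, 1-based inclusive in memory;
* spot table — TSV of replicate spot measurements with QC metadata;
* profile / call matrices — TSV, clones as rows, samples as columns,
  ``NA`` for missing;
* segments — standard SEG (``sample  chrom  loc.start  loc.end
  num.mark  seg.mean``), 1-based inclusive;
* cohort clinical table — CSV;
* region definitions — TSV (``name  chrom  start_clone  end_clone``,
  clone ordinals 0-based inclusive within the chromosome).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}
AUTOSOMES = frozenset(str(i) for i in range(1, 23))

SPOT_COLUMNS = ["sample_id", "clone_id", "replicate", "log2_ratio", "quality_flag", "confidence"]
SEG_COLUMNS = ["sample", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


def normalize_chrom(label: str) -> str:
    """Map a chromosome label to the canonical ``1``–``22``, ``X``, ``Y`` form."""
    lab = str(label).strip()
    if lab.lower().startswith("chr"):
        lab = lab[3:]
    lab = lab.upper() if lab in ("x", "y") or lab.upper() in ("X", "Y") else lab
    if lab not in _CHROM_RANK:
        raise ValidationError(f"unknown chromosome label: {label!r}")
    return lab


class CloneMap:
    """Ordered genomic tiling of array clones; the coordinate backbone.

    Internally coordinates are 1-based inclusive. Clones are sorted by
    (chromosome rank, start), clone ids are unique, clones on one
    chromosome never overlap and every clone has positive length.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"clone_id", "chrom", "start_bp", "end_bp"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"clone map missing columns: {sorted(missing)}")
        df = df.loc[:, ["clone_id", "chrom", "start_bp", "end_bp"]].copy()
        df["chrom"] = [normalize_chrom(c) for c in df["chrom"]]
        df["start_bp"] = df["start_bp"].astype(np.int64)
        df["end_bp"] = df["end_bp"].astype(np.int64)
        if (df["start_bp"] >= df["end_bp"]).any():
            bad = df.loc[df["start_bp"] >= df["end_bp"], "clone_id"].iloc[0]
            raise ValidationError(f"clone {bad!r} has zero or negative length")
        if df["clone_id"].duplicated().any():
            dup = df.loc[df["clone_id"].duplicated(), "clone_id"].iloc[0]
            raise ValidationError(f"duplicate clone_id {dup!r}")
        rank = df["chrom"].map(_CHROM_RANK)
        df = df.assign(_rank=rank).sort_values(["_rank", "start_bp"], kind="mergesort")
        df = df.drop(columns="_rank").reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start_bp"].to_numpy()
            ends = sub["end_bp"].to_numpy()
            if len(sub) > 1 and (starts[1:] <= ends[:-1]).any():
                raise ValidationError(f"overlapping clones on chromosome {chrom}")
        self._df = df
        self._index = {cid: i for i, cid in enumerate(df["clone_id"])}

    # -- basic accessors -------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def n_clones(self) -> int:
        return len(self._df)

    @property
    def clone_ids(self) -> np.ndarray:
        return self._df["clone_id"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self._df["chrom"].to_numpy()

    @property
    def autosomal_mask(self) -> np.ndarray:
        return np.asarray([c in AUTOSOMES for c in self._df["chrom"]])

    def index_of(self, clone_id: str) -> int:
        return self._index[clone_id]

    def chrom_indices(self) -> dict[str, np.ndarray]:
        """Global row indices per chromosome, in map order."""
        out: dict[str, np.ndarray] = {}
        for chrom, sub in self._df.groupby("chrom", sort=False):
            out[chrom] = sub.index.to_numpy()
        return out

    def __len__(self) -> int:
        return self.n_clones

    def __eq__(self, other) -> bool:
        return isinstance(other, CloneMap) and self._df.equals(other._df)


def read_clone_map(path: str | Path) -> CloneMap:
    """Parse a BED-like TSV (``chrom start end clone_id``) into a CloneMap.

    Input coordinates are 0-based half-open (BED); they are stored as
    1-based inclusive. An optional header line is tolerated. Malformed
    lines raise :class:`ParseError` with the line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 tab-separated fields")
            chrom, start_s, end_s, clone_id = fields[:4]
            if lineno == 1 and not _is_int(start_s):
                continue  # header line
            if not (_is_int(start_s) and _is_int(end_s)):
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates")
            start0, end0 = int(start_s), int(end_s)
            if end0 <= start0:
                raise ValidationError(
                    f"{path}: line {lineno}: clone {clone_id!r} has end <= start"
                )
            rows.append((clone_id, chrom, start0 + 1, end0))
    return CloneMap(pd.DataFrame(rows, columns=["clone_id", "chrom", "start_bp", "end_bp"]))


def write_clone_map(clone_map: CloneMap, path: str | Path) -> None:
    """Write a CloneMap back to BED-like TSV (0-based half-open)."""
    df = clone_map.df
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start_bp"] - 1,
            "end": df["end_bp"],
            "clone_id": df["clone_id"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def _is_int(s: str) -> bool:
    try:
        int(s)
    except ValueError:
        return False
    return True


# -- spot tables ---------------------------------------------------------

def validate_spot_table(df: pd.DataFrame, clone_map: CloneMap | None = None) -> pd.DataFrame:
    missing = set(SPOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"spot table missing columns: {sorted(missing)}")
    if (df["replicate"] < 1).any() or (df["replicate"] > 4).any():
        raise ValidationError("replicate index must be in 1..4")
    if clone_map is not None:
        known = set(clone_map.clone_ids)
        unknown = set(df["clone_id"]) - known
        if unknown:
            raise ValidationError(f"spot table references unknown clones: {sorted(unknown)[:5]}")
    return df


def read_spot_table(path: str | Path, clone_map: CloneMap | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_spot_table(df, clone_map)


def write_spot_table(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, SPOT_COLUMNS].to_csv(path, sep="\t", index=False)


# -- profile / call matrices ----------------------------------------------

def write_profile_matrix(profiles: Sequence, clone_map: CloneMap, path: str | Path) -> None:
    """Write per-clone values, clones as rows, samples as columns, NA missing."""
    data = {p.sample_id: np.asarray(p.values, dtype=float) for p in profiles}
    mat = pd.DataFrame(data, index=clone_map.clone_ids)
    mat.index.name = "clone_id"
    mat.to_csv(path, sep="\t", na_rep="NA", float_format="%.6f")


def read_profile_matrix(path: str | Path, clone_map: CloneMap) -> list:
    from .preprocess import SampleProfile  # local import avoids a cycle

    mat = pd.read_csv(path, sep="\t", index_col="clone_id", na_values="NA")
    if list(mat.index) != list(clone_map.clone_ids):
        mat = mat.reindex(clone_map.clone_ids)
    out = []
    for sid in mat.columns:
        vals = mat[sid].to_numpy(dtype=float)
        out.append(SampleProfile(sample_id=str(sid), values=vals,
                                 n_spots_used=np.where(np.isfinite(vals), 1, 0)))
    return out


def write_call_matrix(call_df: pd.DataFrame, path: str | Path) -> None:
    """Write a clones × samples matrix of integer call codes (NA missing)."""
    out = call_df.copy()
    out.index.name = "clone_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def read_call_matrix(path: str | Path, clone_map: CloneMap | None = None) -> pd.DataFrame:
    mat = pd.read_csv(path, sep="\t", index_col="clone_id", na_values="NA")
    if clone_map is not None:
        mat = mat.reindex(clone_map.clone_ids)
    return mat


# -- SEG -------------------------------------------------------------------

def write_seg(profiles: Sequence, clone_map: CloneMap, path: str | Path) -> None:
    """Emit SEG rows (1-based inclusive) for a list of segmented profiles.

    One row per segment; ``num.mark`` counts the informative clones in the
    segment and must be positive.
    """
    df = clone_map.df
    rows = []
    for prof in profiles:
        for seg in prof.segments:
            if seg.n_clones <= 0:
                raise ValidationError(
                    f"sample {prof.sample_id}: segment with 0 markers on {seg.chrom}"
                )
            rows.append(
                (
                    prof.sample_id,
                    seg.chrom,
                    int(df["start_bp"].iat[seg.start_index]),
                    int(df["end_bp"].iat[seg.end_index]),
                    seg.n_clones,
                    seg.mean,
                )
            )
    out = pd.DataFrame(rows, columns=SEG_COLUMNS)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_seg(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SEG_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: SEG file missing columns {sorted(missing)}")
    return df


# -- cohort clinical table -------------------------------------------------

def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a clinical table and derive the responder flag from TRG."""
    from .cohort import assign_response

    if "sample_id" not in df.columns or "trg" not in df.columns:
        raise ValidationError("cohort table needs sample_id and trg columns")
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in cohort table")
    df = df.copy()
    df["trg"] = df["trg"].astype(int)
    df["responder"] = [assign_response(t) for t in df["trg"]]
    return df


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path))


def write_cohort_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# -- region definitions ----------------------------------------------------

@dataclass(frozen=True)
class Region:
    """Named clone-index range: ordinals 0-based inclusive within a chromosome."""

    name: str
    chrom: str
    start_clone: int
    end_clone: int

    def __post_init__(self):
        if self.end_clone < self.start_clone or self.start_clone < 0:
            raise ValidationError(f"region {self.name}: invalid clone range")


def region_clone_indices(region: Region, clone_map: CloneMap) -> np.ndarray:
    """Global clone-map row indices covered by a region."""
    chrom_rows = clone_map.chrom_indices()
    if region.chrom not in chrom_rows:
        raise ValidationError(f"region {region.name}: chromosome {region.chrom} not in map")
    rows = chrom_rows[region.chrom]
    if region.end_clone >= len(rows):
        raise ValidationError(f"region {region.name}: clone range outside chromosome")
    return rows[region.start_clone : region.end_clone + 1]


def read_regions(path: str | Path) -> list[Region]:
    df = pd.read_csv(path, sep="\t")
    return [
        Region(str(r["name"]), normalize_chrom(r["chrom"]), int(r["start_clone"]), int(r["end_clone"]))
        for _, r in df.iterrows()
    ]


def write_regions(regions: Iterable[Region], path: str | Path) -> None:
    pd.DataFrame(
        [(r.name, r.chrom, r.start_clone, r.end_clone) for r in regions],
        columns=["name", "chrom", "start_clone", "end_clone"],
    ).to_csv(path, sep="\t", index=False)
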