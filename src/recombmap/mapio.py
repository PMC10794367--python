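"""Domain types and text I/O for recombination-map pipelines.

Coordinate conventions
----------------------
Internally everything is 0-based, half-open.  Genetic-map text dialects
(Eagle- and HapMap-style) use 1-based positions on disk; the conversion
happens only here, at the I/O boundary.  BED masks are 0-based half-open
on disk and in memory.

The central object is :class:`GeneticMap`: physical positions with
cumulative genetic distance (cM).  The per-interval recombination rate in
cM/Mb is a derived property, so the consistency invariant
``rate[i] == (cum[i+1]-cum[i]) / ((pos[i+1]-pos[i])/1e6)`` holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _intervals

ANCESTRIES = ("PNS", "AFR", "EAS", "EUR")

IBD_COLUMNS = ["id1", "hap1", "id2", "hap2", "chrom", "start_bp", "end_bp", "lod", "length_cM"]


class FormatError(ValueError):
    """A file violated its format contract (message names the line)."""


def _norm_chrom(c: str) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


# ---------------------------------------------------------------------------
# GeneticMap


@dataclass(frozen=True, eq=False)
class GeneticMap:
    """Physical positions with cumulative genetic distance.

    Parameters
    ----------
    chrom : str
        Chromosome label (normalized, no "chr" prefix).
    positions : ndarray of int
        0-based physical positions, strictly increasing.
    cum_cM : ndarray of float
        Cumulative genetic distance at each position, non-decreasing,
        ``cum_cM[0] >= 0``.
    """

    chrom: str
    positions: np.ndarray
    cum_cM: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=np.int64)
        cum = np.asarray(self.cum_cM, dtype=np.float64)
        object.__setattr__(self, "chrom", _norm_chrom(self.chrom))
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "cum_cM", cum)
        if pos.ndim != 1 or pos.size < 1 or pos.size != cum.size:
            raise ValueError("positions and cum_cM must be 1-d and equal length >= 1")
        if pos.size > 1 and np.any(np.diff(pos) <= 0):
            i = int(np.argmax(np.diff(pos) <= 0))
            raise ValueError(f"positions not strictly increasing at index {i + 1}")
        if np.any(np.diff(cum) < -1e-12) or cum[0] < 0:
            raise ValueError("cum_cM must be non-negative and non-decreasing")

    @classmethod
    def from_rates(cls, chrom, positions, rate_cM_per_Mb, start_cM: float = 0.0) -> "GeneticMap":
        """Build a map from per-interval rates by piecewise-constant integration."""
        pos = np.asarray(positions, dtype=np.int64)
        rate = np.asarray(rate_cM_per_Mb, dtype=np.float64)
        if rate.size != pos.size - 1:
            raise ValueError("need one rate per interval (len(positions) - 1)")
        if np.any(rate < 0):
            raise ValueError("negative recombination rate")
        seg_cM = rate * np.diff(pos) / 1e6
        cum = np.concatenate([[start_cM], start_cM + np.cumsum(seg_cM)])
        return cls(chrom, pos, cum)

    # derived ------------------------------------------------------------
    @property
    def rate_cM_per_Mb(self) -> np.ndarray:
        return np.diff(self.cum_cM) / (np.diff(self.positions) / 1e6)

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    @property
    def total_cM(self) -> float:
        return float(self.cum_cM[-1] - self.cum_cM[0])

    @property
    def span(self) -> tuple[int, int]:
        return int(self.positions[0]), int(self.positions[-1])

    # queries ------------------------------------------------------------
    def interpolate_cM(self, bp):
        """Genetic position of ``bp`` by linear interpolation.

        Total function: positions outside the map clamp to the terminal
        cumulative values (zero-rate extrapolation).
        """
        return np.interp(bp, self.positions, self.cum_cM)

    def interpolate_bp(self, cM):
        """Inverse interpolation: physical position at genetic position ``cM``."""
        return np.interp(cM, self.cum_cM, self.positions)

    def scaled(self, factor: float) -> "GeneticMap":
        """Map with every rate (hence every genetic distance) multiplied by ``factor``."""
        return GeneticMap(self.chrom, self.positions, self.cum_cM * factor)

    def allclose(self, other: "GeneticMap", rtol=1e-9, atol=1e-12) -> bool:
        return (
            self.chrom == other.chrom
            and self.positions.size == other.positions.size
            and bool(np.all(self.positions == other.positions))
            and bool(np.allclose(self.cum_cM, other.cum_cM, rtol=rtol, atol=atol))
        )


def rescale_region(gmap: GeneticMap, start: int, end: int, factor: float) -> GeneticMap:
    """Multiply the recombination rate by ``factor`` over ``[start, end)``.

    Map intervals partially overlapping the region are split at its
    boundaries so the scaling is exact in bp.
    """
    pos = gmap.positions
    extra = [b for b in (start, end) if pos[0] < b < pos[-1] and b not in pos]
    newpos = np.unique(np.concatenate([pos, np.asarray(extra, dtype=np.int64)]))
    cum = gmap.interpolate_cM(newpos)
    rate = np.diff(cum) / (np.diff(newpos) / 1e6)
    mid = (newpos[:-1] + newpos[1:]) / 2
    inside = (mid >= start) & (mid < end)
    rate[inside] *= factor
    return GeneticMap.from_rates(gmap.chrom, newpos, rate, start_cM=float(cum[0]))


# ---------------------------------------------------------------------------
# Genetic-map text dialects

_DIALECT_HEADERS = {
    "eagle3col": "chr position COMBINED_rate(cM/Mb) Genetic_Map(cM)",
    "hapmap4col": "Chromosome\tPosition(bp)\tRate(cM/Mb)\tMap(cM)",
}


def write_genetic_map(gmap: GeneticMap, path, dialect: str = "eagle3col") -> None:
    if dialect not in _DIALECT_HEADERS:
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = " " if dialect == "eagle3col" else "\t"
    chrom = gmap.chrom if dialect == "eagle3col" else f"chr{gmap.chrom}"
    rate = np.concatenate([gmap.rate_cM_per_Mb, [0.0]])
    lines = [_DIALECT_HEADERS[dialect]]
    for p, r, c in zip(gmap.positions, rate, gmap.cum_cM):
        # 1-based positions on disk; shortest-exact float repr for round-trips
        lines.append(sep.join([chrom, str(int(p) + 1), repr(float(r)), repr(float(c))]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genetic_map(path, dialect: str = "eagle3col") -> GeneticMap:
    """Parse a genetic-map text file.

    Both dialects carry four columns (chrom, 1-based position, rate cM/Mb,
    cumulative cM); they differ in header and separator and are tolerated
    with or without ``chr`` prefixes.  Cumulative cM is taken from the file;
    the rate column is validated for non-negativity.
    """
    if dialect not in _DIALECT_HEADERS:
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    chroms, pos, rate, cum = [], [], [], []
    for ln_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(f"{path}: line {ln_no}: expected 4 columns, got {len(parts)}")
        try:
            p = int(parts[1])
            r = float(parts[2])
            c = float(parts[3])
        except ValueError as exc:
            raise FormatError(f"{path}: line {ln_no}: {exc}") from None
        if r < 0:
            raise FormatError(f"{path}: line {ln_no}: negative rate {r}")
        if pos and p <= pos[-1]:
            raise FormatError(f"{path}: line {ln_no}: position {p} not increasing")
        chroms.append(_norm_chrom(parts[0]))
        pos.append(p)
        rate.append(r)
        cum.append(c)
    if len(set(chroms)) != 1:
        raise FormatError(f"{path}: expected exactly one chromosome, got {sorted(set(chroms))}")
    return GeneticMap(chroms[0], np.asarray(pos, dtype=np.int64) - 1, cum)


# ---------------------------------------------------------------------------
# Rho windows (LDhat interval-style output, already summarized per interval)


@dataclass(frozen=True, eq=False)
class RhoWindow:
    """One analysis window of population-scaled recombination estimates.

    ``rho_per_kb[i]`` is the estimate of rho = 4*Ne*r (per kb) on the
    interval between ``snp_positions[i]`` and ``snp_positions[i+1]``.
    """

    chrom: str
    window_index: int
    snp_positions: np.ndarray
    rho_per_kb: np.ndarray
    n_overlap_left: int = 0
    n_overlap_right: int = 0

    def __post_init__(self):
        pos = np.asarray(self.snp_positions, dtype=np.int64)
        rho = np.asarray(self.rho_per_kb, dtype=np.float64)
        object.__setattr__(self, "snp_positions", pos)
        object.__setattr__(self, "rho_per_kb", rho)
        if rho.size != pos.size - 1:
            raise ValueError("need one rho per SNP interval")
        if pos.size > 1 and np.any(np.diff(pos) <= 0):
            raise ValueError("snp_positions not strictly increasing")
        if np.any(rho < 0):
            raise ValueError("negative rho")
        if self.n_overlap_left >= pos.size or self.n_overlap_right >= pos.size:
            raise ValueError("overlap count must be smaller than the window")


@dataclass(frozen=True)
class RhoWindowSet:
    chrom: str
    windows: tuple

    def __len__(self):
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)


# ---------------------------------------------------------------------------
# MaskSet and BED


class MaskSet:
    """Sorted, disjoint, half-open genomic intervals per chromosome.

    Abutting or overlapping intervals are merged on construction, so every
    MaskSet is in canonical form and total masked length is well defined.
    """

    def __init__(self, intervals: dict | None = None):
        self._iv: dict[str, np.ndarray] = {}
        for chrom, iv in (intervals or {}).items():
            iv = _intervals.as_intervals(iv)
            if iv.shape[0]:
                self._iv[_norm_chrom(chrom)] = _intervals.normalize(iv)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._iv)

    def intervals(self, chrom) -> np.ndarray:
        return self._iv.get(_norm_chrom(chrom), np.zeros((0, 2), dtype=np.int64))

    def total_bp(self) -> int:
        return sum(_intervals.total_length(iv) for iv in self._iv.values())

    def __eq__(self, other):
        if not isinstance(other, MaskSet):
            return NotImplemented
        if set(self._iv) != set(other._iv):
            return False
        return all(np.array_equal(self._iv[c], other._iv[c]) for c in self._iv)

    def __repr__(self):
        n = sum(iv.shape[0] for iv in self._iv.values())
        return f"MaskSet({n} intervals, {self.total_bp()} bp, chroms={self.chroms})"


def write_bed(mask: MaskSet, path) -> None:
    with open(path, "w") as fh:
        for chrom in mask.chroms:
            for s, e in mask.intervals(chrom):
                fh.write(f"{chrom}\t{s}\t{e}\n")


def read_bed(path) -> MaskSet:
    iv: dict[str, list] = {}
    for ln_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}: line {ln_no}: expected >= 3 columns")
        try:
            s, e = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise FormatError(f"{path}: line {ln_no}: {exc}") from None
        if e <= s:
            raise FormatError(f"{path}: line {ln_no}: end <= start")
        iv.setdefault(_norm_chrom(parts[0]), []).append((s, e))
    return MaskSet(iv)


# ---------------------------------------------------------------------------
# IBD segment tables (Refined IBD tab layout)


def validate_ibd(df: pd.DataFrame) -> pd.DataFrame:
    df = df.reset_index(drop=True)
    if np.any(df["end_bp"] <= df["start_bp"]):
        i = int(np.argmax((df["end_bp"] <= df["start_bp"]).to_numpy()))
        raise ValueError(f"IBD segment row {i}: end_bp <= start_bp")
    if np.any(df["length_cM"] < 0):
        raise ValueError("negative IBD segment genetic length")
    if not df["hap1"].isin([1, 2]).all() or not df["hap2"].isin([1, 2]).all():
        raise ValueError("haplotype index must be 1 or 2")
    same = (df["id1"] == df["id2"]) & (df["hap1"] == df["hap2"])
    if same.any():
        raise ValueError("segment pairs a haplotype with itself")
    return df


def read_ibd_table(path) -> pd.DataFrame:
    """Read a Refined-IBD style tab file into an IBD segment table.

    Columns on disk: sample1, hap1, sample2, hap2, chrom, start, end, LOD, cM.
    """
    rows = []
    for ln_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 9:
            raise FormatError(f"{path}: line {ln_no}: expected 9 columns, got {len(parts)}")
        try:
            rows.append(
                (
                    parts[0],
                    int(parts[1]),
                    parts[2],
                    int(parts[3]),
                    _norm_chrom(parts[4]),
                    int(parts[5]),
                    int(parts[6]),
                    float(parts[7]),
                    float(parts[8]),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {ln_no}: {exc}") from None
        if rows[-1][6] <= rows[-1][5]:
            raise FormatError(f"{path}: line {ln_no}: end <= start")
    df = pd.DataFrame(rows, columns=IBD_COLUMNS)
    return validate_ibd(df)


def write_ibd_table(df: pd.DataFrame, path) -> None:
    validate_ibd(df)
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(
                "\t".join(
                    [
                        str(row.id1),
                        str(int(row.hap1)),
                        str(row.id2),
                        str(int(row.hap2)),
                        str(row.chrom),
                        str(int(row.start_bp)),
                        str(int(row.end_bp)),
                        repr(float(row.lod)),
                        repr(float(row.length_cM)),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Local-ancestry tracks (RFMIX msp-style with marginal probabilities)


@dataclass(frozen=True, eq=False)
class AncestryTrack:
    """Per-site, per-haplotype ancestry calls with marginal probabilities.

    ``calls`` has shape (n_sites, n_ind, 2) with integer codes indexing
    ``ANCESTRIES``; ``probs`` has shape (n_sites, n_ind, 2, 4) and each
    probability vector sums to 1 (within 1e-6).
    """

    chrom: str
    positions: np.ndarray
    calls: np.ndarray
    probs: np.ndarray
    individuals: tuple = ()

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=np.int64)
        calls = np.asarray(self.calls, dtype=np.int8)
        probs = np.asarray(self.probs, dtype=np.float64)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "calls", calls)
        object.__setattr__(self, "probs", probs)
        n_sites, n_ind = calls.shape[0], calls.shape[1]
        if not self.individuals:
            object.__setattr__(self, "individuals", tuple(f"ind{i}" for i in range(n_ind)))
        if calls.shape != (n_sites, n_ind, 2) or probs.shape != (n_sites, n_ind, 2, 4):
            raise ValueError("calls/probs shape mismatch")
        if pos.size != n_sites:
            raise ValueError("positions length mismatch")
        if not np.allclose(probs.sum(axis=-1), 1.0, atol=1e-6):
            raise ValueError("marginal probability vectors must sum to 1")

    @property
    def n_ind(self) -> int:
        return self.calls.shape[1]


def write_ancestry_track(track: AncestryTrack, path) -> None:
    codes = " ".join(f"{a}={i}" for i, a in enumerate(ANCESTRIES))
    cols = ["#chm", "pos"]
    for ind in track.individuals:
        for h in (0, 1):
            cols.append(f"{ind}.{h}")
            cols.extend(f"{ind}.{h}.p{a}" for a in ANCESTRIES)
    with open(path, "w") as fh:
        fh.write(f"#Subpopulation order/codes: {codes}\n")
        fh.write("\t".join(cols) + "\n")
        for i, p in enumerate(track.positions):
            fields = [track.chrom, str(int(p))]
            for j in range(track.n_ind):
                for h in (0, 1):
                    fields.append(str(int(track.calls[i, j, h])))
                    fields.extend(repr(float(x)) for x in track.probs[i, j, h])
            fh.write("\t".join(fields) + "\n")


def read_ancestry_track(path) -> AncestryTrack:
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3 or not lines[0].startswith("#Subpopulation"):
        raise FormatError(f"{path}: not an ancestry track file")
    header = lines[1].split("\t")
    ind_names = []
    for name in header[2::10]:
        ind_names.append(name.rsplit(".", 1)[0])
    n_ind = len(ind_names)
    positions, calls, probs, chrom = [], [], [], None
    for ln_no, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2 + 10 * n_ind:
            raise FormatError(f"{path}: line {ln_no}: wrong column count")
        chrom = parts[0]
        positions.append(int(parts[1]))
        row_calls = np.empty((n_ind, 2), dtype=np.int8)
        row_probs = np.empty((n_ind, 2, 4))
        for j in range(n_ind):
            for h in (0, 1):
                base = 2 + 10 * j + 5 * h
                row_calls[j, h] = int(parts[base])
                row_probs[j, h] = [float(x) for x in parts[base + 1 : base + 5]]
        calls.append(row_calls)
        probs.append(row_probs)
    return AncestryTrack(chrom, positions, np.array(calls), np.array(probs), tuple(ind_names))


# ---------------------------------------------------------------------------
# Normalized score tracks (selscan-style)

SCORE_COLUMNS = ["pos", "freq", "ihs", "z"]


def write_score_track(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SCORE_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            fh.write(
                f"{int(row.pos)}\t{repr(float(row.freq))}\t"
                f"{repr(float(row.ihs))}\t{repr(float(row.z))}\n"
            )


def read_score_track(path) -> pd.DataFrame:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != SCORE_COLUMNS:
        raise FormatError(f"{path}: missing score-track header")
    rows = []
    for ln_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(f"{path}: line {ln_no}: expected 4 columns")
        try:
            rows.append((int(parts[0]), float(parts[1]), float(parts[2]), float(parts[3])))
        except ValueError as exc:
            raise FormatError(f"{path}: line {ln_no}: {exc}") from None
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)
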