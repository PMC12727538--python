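"""Genomic interval plumbing shared by every analysis stage.

Coordinates are 0-based half-open throughout (BED semantics). Strand is
ignored: nothing downstream (window enrichment, amplicon annotation, peak
overlap) is stranded. The two containers are deliberately thin: a
:class:`GenomeLayout` is an ordered chrom → length map (chrom.sizes dialect)
and an :class:`IntervalSet` wraps a pandas DataFrame with ``chrom``,
``start``, ``end`` (plus optional extra columns such as ``name``/``score``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "IntervalSet",
    "read_bed",
    "read_chrom_sizes",
    "bin_genome",
    "coverage_fraction_overlap",
    "covered_bases",
    "count_overlaps",
    "merge_adjacent",
    "sample_matched_random_intervals",
]

BED_COLUMNS = ("chrom", "start", "end")


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered reference sequence names and lengths (in bp)."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence names in layout")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("all sequence lengths must be > 0")

    @classmethod
    def from_dict(cls, sizes: Mapping[str, int]) -> "GenomeLayout":
        return cls(tuple(sizes), tuple(int(v) for v in sizes.values()))

    @property
    def sizes(self) -> dict[str, int]:
        return dict(zip(self.names, self.lengths))

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def length_of(self, name: str) -> int:
        try:
            return self.lengths[self.names.index(name)]
        except ValueError:
            raise KeyError(f"unknown sequence name: {name!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.names, "length": self.lengths})

    def write_chrom_sizes(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Read a two-column name/length TSV (UCSC chrom.sizes dialect)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["chrom", "length"])
    return GenomeLayout(tuple(df["chrom"].astype(str)), tuple(int(v) for v in df["length"]))


class IntervalSet:
    """An ordered collection of genomic intervals backed by a DataFrame.

    Invariants enforced at construction: integer coordinates with
    ``0 <= start < end``. Order of the input is preserved; operations that
    need sorted input sort internally without mutating the set.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.reset_index(drop=True).copy()
        for col in BED_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"IntervalSet requires column {col!r}")
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df) and (df["start"] < 0).any():
            raise ValueError("negative start coordinate")
        if len(df) and (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]][0]
            raise ValueError(f"interval {bad} has start >= end")
        self.df = df

    # ---- constructors -------------------------------------------------
    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int]], names: Sequence[str] | None = None
    ) -> "IntervalSet":
        df = pd.DataFrame(records, columns=list(BED_COLUMNS))
        if names is not None:
            df["name"] = list(names)
        return cls(df)

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls(pd.DataFrame({c: [] for c in BED_COLUMNS}))

    # ---- basics -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:  # pragma: no cover
        return f"IntervalSet({len(self)} intervals)"

    @property
    def chroms(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def starts(self) -> np.ndarray:
        return self.df["start"].to_numpy()

    @property
    def ends(self) -> np.ndarray:
        return self.df["end"].to_numpy()

    @property
    def widths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2

    def validate_against(self, layout: GenomeLayout) -> None:
        sizes = layout.sizes
        for chrom, end in zip(self.chroms, self.ends):
            if chrom not in sizes:
                raise KeyError(f"unknown sequence name: {chrom!r}")
            if end > sizes[chrom]:
                raise ValueError(f"interval end {end} exceeds length of {chrom}")

    def subset(self, mask: np.ndarray) -> "IntervalSet":
        return IntervalSet(self.df.loc[np.asarray(mask)])

    def write_bed(self, path: str | Path) -> None:
        cols = [c for c in ("chrom", "start", "end", "name", "score") if c in self.df.columns]
        self.df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> IntervalSet:
    """Parse a BED3+ file (0-based half-open), preserving record order.

    ``track``/``browser``/``#`` lines are skipped. Malformed lines raise a
    ``ValueError`` naming the offending line number.
    """
    records: list[tuple] = []
    names: list[str] = []
    scores: list[str] = []
    has_name = has_score = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            records.append((fields[0], start, end))
            if len(fields) >= 4:
                has_name = True
                names.append(fields[3])
            else:
                names.append("")
            if len(fields) >= 5:
                has_score = True
                scores.append(fields[4])
            else:
                scores.append("")
    df = pd.DataFrame(records, columns=list(BED_COLUMNS))
    if has_name:
        df["name"] = names
    if has_score:
        df["score"] = scores
    return IntervalSet(df)


def bin_genome(layout: GenomeLayout, bin_size: int) -> IntervalSet:
    """Tile every sequence with consecutive bins; the final partial bin is kept."""
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    frames = []
    for chrom, length in zip(layout.names, layout.lengths):
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return IntervalSet(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# sorted-array machinery


def _merged_by_chrom(iset: IntervalSet, max_gap: int = 0) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Union-merge intervals per chromosome; returns sorted disjoint arrays."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if len(iset) == 0:
        return out
    df = iset.df.sort_values(["chrom", "start", "end"], kind="mergesort")
    for chrom, sub in df.groupby("chrom", sort=False):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        run_max = np.maximum.accumulate(e)
        # a new merged block starts where the gap to everything before exceeds max_gap
        new_block = np.ones(len(s), dtype=bool)
        new_block[1:] = s[1:] > run_max[:-1] + max_gap
        block = np.cumsum(new_block) - 1
        ms = s[new_block]
        me = np.maximum.reduceat(e, np.flatnonzero(new_block))
        # reduceat gives block-wise max of e; equals merged ends
        del block
        out[str(chrom)] = (ms, me)
    return out


def merge_adjacent(iset: IntervalSet, max_gap: int = 0) -> IntervalSet:
    """Merge same-chromosome intervals whose gap is <= ``max_gap`` bp.

    Output is sorted and non-overlapping; extra columns are dropped.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    merged = _merged_by_chrom(iset, max_gap=max_gap)
    frames = [
        pd.DataFrame({"chrom": chrom, "start": s, "end": e})
        for chrom, (s, e) in sorted(merged.items())
    ]
    if not frames:
        return IntervalSet.empty()
    return IntervalSet(pd.concat(frames, ignore_index=True))


def covered_bases(query: IntervalSet, subject: IntervalSet) -> np.ndarray:
    """Bases of each query interval covered by the *union* of subject intervals."""
    merged = _merged_by_chrom(subject)
    out = np.zeros(len(query), dtype=np.int64)
    if not merged or len(query) == 0:
        return out
    for chrom, idx in query.df.groupby("chrom", sort=False).groups.items():
        if chrom not in merged:
            continue
        ms, me = merged[chrom]
        cum = np.concatenate(([0], np.cumsum(me - ms)))
        a = query.df.loc[idx, "start"].to_numpy()
        b = query.df.loc[idx, "end"].to_numpy()
        i0 = np.searchsorted(me, a, side="right")   # first block ending after a
        i1 = np.searchsorted(ms, b, side="left") - 1  # last block starting before b
        cov = np.zeros(len(a), dtype=np.int64)
        hit = i0 <= i1
        if hit.any():
            ia, ib = i0[hit], i1[hit]
            total = cum[ib + 1] - cum[ia]
            left_trim = np.maximum(0, a[hit] - ms[ia])
            right_trim = np.maximum(0, me[ib] - b[hit])
            cov[hit] = total - left_trim - right_trim
        out[np.asarray(idx)] = cov
    return out


def coverage_fraction_overlap(
    query: IntervalSet,
    subject: IntervalSet,
    min_frac: float,
    strict: bool = False,
) -> np.ndarray:
    """Per-query boolean: union-covered fraction of the query >= (or >) ``min_frac``.

    The non-strict comparator (>=) is the default; ``strict=True`` uses >.
    """
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must be in (0, 1]")
    cov = covered_bases(query, subject)
    frac = cov / query.widths
    return frac > min_frac if strict else frac >= min_frac


def count_overlaps(query: IntervalSet, subject: IntervalSet) -> np.ndarray:
    """Number of subject intervals overlapping (>=1 bp) each query interval."""
    out = np.zeros(len(query), dtype=np.int64)
    if len(subject) == 0 or len(query) == 0:
        return out
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in subject.df.groupby("chrom", sort=False):
        by_chrom[str(chrom)] = (
            np.sort(sub["start"].to_numpy()),
            np.sort(sub["end"].to_numpy()),
        )
    for chrom, idx in query.df.groupby("chrom", sort=False).groups.items():
        if chrom not in by_chrom:
            continue
        starts_sorted, ends_sorted = by_chrom[chrom]
        a = query.df.loc[idx, "start"].to_numpy()
        b = query.df.loc[idx, "end"].to_numpy()
        n_start_before = np.searchsorted(starts_sorted, b, side="left")
        n_end_before = np.searchsorted(ends_sorted, a, side="right")
        out[np.asarray(idx)] = n_start_before - n_end_before
    return out


def _intersects_any(chrom: str, start: int, end: int,
                    merged: dict[str, tuple[np.ndarray, np.ndarray]]) -> bool:
    if chrom not in merged:
        return False
    ms, me = merged[chrom]
    i = np.searchsorted(me, start, side="right")
    return i < len(ms) and ms[i] < end


def sample_matched_random_intervals(
    template: IntervalSet,
    layout: GenomeLayout,
    exclude: IntervalSet | None = None,
    seed: int | np.random.Generator | None = None,
    max_tries: int = 1000,
) -> IntervalSet:
    """Draw one random interval per template interval, of identical width.

    The start is uniform over every valid placement genome-wide (any
    chromosome long enough), rejecting draws that intersect ``exclude``.
    Deterministic for a fixed seed. Raises if a width admits no accepted
    placement within ``max_tries`` draws.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    merged_excl = _merged_by_chrom(exclude) if exclude is not None and len(exclude) else {}
    lengths = np.asarray(layout.lengths, dtype=np.int64)
    records = []
    for w in template.widths:
        slots = np.maximum(0, lengths - w + 1)
        total = slots.sum()
        if total <= 0:
            raise ValueError(f"no sequence can hold an interval of width {w}")
        cum = np.cumsum(slots)
        placed = False
        for _ in range(max_tries):
            u = int(rng.integers(total))
            ci = int(np.searchsorted(cum, u, side="right"))
            start = int(u - (cum[ci - 1] if ci else 0))
            chrom = layout.names[ci]
            if not _intersects_any(chrom, start, start + int(w), merged_excl):
                records.append((chrom, start, start + int(w)))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"no valid placement for width {w} after {max_tries} tries "
                "(exclude set too dense?)"
            )
    return IntervalSet.from_records(records)
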