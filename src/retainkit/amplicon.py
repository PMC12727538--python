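"""Retention-element landscape analyses over classified amplicon catalogs,
plus generic interval-set enrichment.

A catalog is a DataFrame with one row per amplified genomic interval:
``sample, amplicon_id, class (ecDNA|BFB|linear), chrom, start, end`` and
optionally ``oncogenes``. Element overlap counting uses the any-overlap
(>= 1 bp) rule; fractional-coverage thresholds appear only in the
enrichment operations that state them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import (
    GenomeLayout,
    IntervalSet,
    count_overlaps,
    coverage_fraction_overlap,
    sample_matched_random_intervals,
)
from .stats import (
    bh_fdr,
    fisher_exact_2x2,
    fisher_z_compare,
    hypergeom_upper_tail,
    pearson_with_ci,
    two_proportion_z,
)

__all__ = [
    "annotate_intervals",
    "local_re_density",
    "amplicon_summaries",
    "coamplification_rates",
    "oncogene_re_enrichment",
    "density_size_correlation",
    "interval_set_enrichment",
    "EnrichmentResult",
]

AMPLICON_CLASSES = ("ecDNA", "BFB", "linear")


def _catalog_intervals(catalog: pd.DataFrame) -> IntervalSet:
    return IntervalSet(catalog[["chrom", "start", "end"]])


def annotate_intervals(
    catalog: pd.DataFrame,
    re_set: IntervalSet,
    oncogenes: IntervalSet | None = None,
    layout: GenomeLayout | None = None,
) -> pd.DataFrame:
    """Add ``width``, ``n_re`` (any-overlap element count) and, when an
    oncogene catalog is given, a semicolon-separated ``oncogenes`` column."""
    ivals = _catalog_intervals(catalog)
    if layout is not None:
        ivals.validate_against(layout)
        re_set.validate_against(layout)
    out = catalog.copy()
    out["width"] = ivals.widths
    out["n_re"] = count_overlaps(ivals, re_set)
    if oncogenes is not None:
        names = oncogenes.df.get("name", pd.Series([""] * len(oncogenes)))
        hits: list[str] = []
        for chrom, start, end in zip(ivals.chroms, ivals.starts, ivals.ends):
            sub = oncogenes.df[
                (oncogenes.df["chrom"] == chrom)
                & (oncogenes.df["start"] < end)
                & (oncogenes.df["end"] > start)
            ]
            hits.append(";".join(names.loc[sub.index].astype(str)))
        out["oncogenes"] = hits
    return out


def local_re_density(
    catalog: pd.DataFrame, re_set: IntervalSet, half_window: float = 2.5e6
) -> pd.DataFrame:
    """Local retention-element density per interval (elements per Mb).

    Interval density = number of elements with any overlap of
    [midpoint - half_window, midpoint + half_window) divided by the window
    width in Mb (the denominator stays the full window even at chromosome
    ends). Adds a ``local_density`` column.
    """
    if half_window <= 0:
        raise ValueError("half_window must be > 0")
    ivals = _catalog_intervals(catalog)
    mids = ivals.midpoints
    win = IntervalSet(
        pd.DataFrame(
            {
                "chrom": ivals.chroms,
                "start": np.maximum(0, mids - int(half_window)),
                "end": mids + int(half_window),
            }
        )
    )
    # windows clipped at 0 keep the fixed 5-Mb denominator
    n = count_overlaps(win, re_set)
    out = catalog.copy()
    out["local_density"] = n / (2 * half_window / 1e6)
    return out


def amplicon_summaries(annotated: pd.DataFrame) -> pd.DataFrame:
    """Per-amplicon totals: size, width-weighted local density, flags.

    Requires ``width``, ``n_re`` and ``local_density`` columns (from
    :func:`annotate_intervals` and :func:`local_re_density`).
    """
    rows = []
    for (sample, amp), sub in annotated.groupby(["sample", "amplicon_id"]):
        w = sub["width"].to_numpy(dtype=float)
        rows.append(
            {
                "sample": sample,
                "amplicon_id": amp,
                "class": sub["class"].iloc[0],
                "total_size": float(w.sum()),
                "weighted_density": float((sub["local_density"] * w).sum() / w.sum()),
                "has_re_negative_interval": bool((sub["n_re"] == 0).any()),
                "has_re_positive_interval": bool((sub["n_re"] > 0).any()),
            }
        )
    out = pd.DataFrame(rows)
    out["coamplified"] = out["has_re_negative_interval"] & out["has_re_positive_interval"]
    return out


def coamplification_rates(
    summaries: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    continuity: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class co-amplification proportions and one-sided tests.

    Denominator per class: amplicons containing at least one
    element-negative interval; numerator: those that also contain an
    element-positive interval (counted once per amplicon). Pairs are tested
    one-sided (first class proportion > second) with the pooled
    two-proportion z.
    """
    rates = []
    for klass, sub in summaries.groupby("class"):
        denom = sub["has_re_negative_interval"].sum()
        num = sub["coamplified"].sum()
        if denom == 0:
            import warnings

            warnings.warn(f"class {klass!r} has no element-negative amplicons; skipped")
            continue
        rates.append(
            {"class": klass, "n_coamplified": int(num), "n_eligible": int(denom),
             "proportion": num / denom}
        )
    rates_df = pd.DataFrame(rates)
    lookup = rates_df.set_index("class")
    if pairs is None:
        pairs = [("ecDNA", "linear"), ("BFB", "linear")]
    tests = []
    for a, b in pairs:
        if a not in lookup.index or b not in lookup.index:
            continue
        z, p = two_proportion_z(
            int(lookup.loc[a, "n_coamplified"]), int(lookup.loc[a, "n_eligible"]),
            int(lookup.loc[b, "n_coamplified"]), int(lookup.loc[b, "n_eligible"]),
            alternative="larger", continuity=continuity,
        )
        tests.append({"class_a": a, "class_b": b, "z": z, "p": p})
    return rates_df, pd.DataFrame(tests)


def oncogene_re_enrichment(
    observed: pd.DataFrame,
    oncogene: tuple[str, int, int],
    re_set: IntervalSet,
    layout: GenomeLayout,
    n_random: int = 100,
    max_dist: float = 5e5,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Element-level enrichment in observed oncogene-containing intervals
    versus random same-width oncogene-containing placements.

    For every observed interval, ``n_random`` intervals of the same width are
    drawn uniformly over start positions that keep the full oncogene span
    inside the interval (and the interval inside the chromosome). For each
    retention element whose midpoint lies within ``max_dist`` of the
    oncogene midpoint, the observed inclusion frequency is compared with the
    pooled random frequency: fold change observed/expected, two-sided
    Fisher's exact test on the 2×2 inclusion table, BH adjustment across the
    elements of this oncogene. Elements never included in random intervals
    are reported as not estimable (NaN fold change).
    """
    chrom, o_start, o_end = oncogene
    chrom_len = layout.length_of(chrom)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    widths = (observed["end"] - observed["start"]).to_numpy()
    if (widths < o_end - o_start).any():
        raise ValueError("an observed interval is narrower than the oncogene span")

    o_mid = (o_start + o_end) // 2
    edf = re_set.df
    emid = (edf["start"].to_numpy() + edf["end"].to_numpy()) // 2
    cand = (edf["chrom"].to_numpy() == chrom) & (np.abs(emid - o_mid) <= max_dist)
    cand_idx = np.flatnonzero(cand)
    if len(cand_idx) == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "obs_freq", "exp_freq",
                     "fold_change", "p", "fdr", "estimable"]
        )

    es = edf["start"].to_numpy()[cand_idx]
    ee = edf["end"].to_numpy()[cand_idx]

    def inclusion(starts: np.ndarray, w: int) -> np.ndarray:
        """Any-overlap of each candidate element with intervals [s, s+w)."""
        # result: candidates x placements summed over placements
        s = starts[:, None]
        return ((s < ee[None, :]) & (s + w > es[None, :])).sum(axis=0)

    obs_starts = observed["start"].to_numpy()
    obs_in = np.zeros(len(cand_idx), dtype=np.int64)
    rand_in = np.zeros(len(cand_idx), dtype=np.int64)
    n_obs = len(observed)
    n_rand_total = 0
    for s0, w in zip(obs_starts, widths):
        w = int(w)
        obs_in += ((s0 < ee) & (s0 + w > es)).astype(np.int64)
        lo = max(0, o_end - w)
        hi = min(o_start, chrom_len - w)
        if hi < lo:
            raise ValueError("oncogene span cannot fit inside the chromosome with this width")
        starts = rng.integers(lo, hi + 1, size=n_random)
        rand_in += inclusion(starts, w)
        n_rand_total += n_random

    obs_freq = obs_in / n_obs
    exp_freq = rand_in / n_rand_total
    estimable = rand_in > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(estimable, obs_freq / np.where(estimable, exp_freq, 1.0), np.nan)
    pvals = np.array(
        [
            fisher_exact_2x2(
                [[obs_in[i], n_obs - obs_in[i]],
                 [rand_in[i], n_rand_total - rand_in[i]]]
            )
            for i in range(len(cand_idx))
        ]
    )
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": es,
            "end": ee,
            "obs_freq": obs_freq,
            "exp_freq": exp_freq,
            "fold_change": fc,
            "p": pvals,
            "fdr": bh_fdr(pvals),
            "estimable": estimable,
        }
    )


def density_size_correlation(
    summaries: pd.DataFrame,
    classes: tuple[str, ...] = AMPLICON_CLASSES,
    log_size: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class Pearson R (with Fisher-transform 95% CI) between local
    element density and amplicon size, and pairwise Fisher z comparisons.

    Size is log10-transformed by default (amplicon sizes span orders of
    magnitude); ``log_size=False`` correlates raw sizes.
    """
    per_class = []
    ests = {}
    for klass in classes:
        sub = summaries[summaries["class"] == klass]
        if len(sub) < 4:
            raise ValueError(f"need >= 4 amplicons in class {klass!r}")
        size = sub["total_size"].to_numpy(dtype=float)
        x = np.log10(size) if log_size else size
        est = pearson_with_ci(sub["weighted_density"].to_numpy(), x)
        ests[klass] = est
        per_class.append(
            {"class": klass, "r": est.r, "ci_low": est.ci_low,
             "ci_high": est.ci_high, "n": est.n, "p": est.p}
        )
    pair_rows = []
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            z, p = fisher_z_compare(ests[a].r, ests[a].n, ests[b].r, ests[b].n)
            pair_rows.append({"class_a": a, "class_b": b, "z": z, "p": p})
    return pd.DataFrame(per_class), pd.DataFrame(pair_rows)


@dataclass(frozen=True)
class EnrichmentResult:
    """Result of one interval-set enrichment comparison."""

    observed_count: int
    n_query: int
    observed_frac: float
    expected_frac: float
    fold_change: float
    log2fc: float
    p: float | None
    test: str


def interval_set_enrichment(
    query: IntervalSet,
    annotation: IntervalSet,
    coverage_frac: float,
    test: str = "fisher",
    background: IntervalSet | None = None,
    layout: GenomeLayout | None = None,
    genome_bins: IntervalSet | None = None,
    exclude: IntervalSet | None = None,
    seed: int | np.random.Generator | None = None,
    strict: bool = False,
) -> EnrichmentResult:
    """Enrichment of an annotation in a query interval set.

    Overlap calls require the annotation union to cover at least
    ``coverage_frac`` of an interval. Modes:

    * ``fisher`` — 2×2 table of query vs matched-size random intervals
      (``background`` if given, else drawn from ``layout``), two-sided
      Fisher's exact test;
    * ``hypergeometric`` — genome bins as the urn (bins overlapped by the
      annotation are the successes; the query intervals the draws),
      upper-tail p;
    * ``log2fc`` — log2(query fraction / background fraction), no p-value.
    """
    if len(query) == 0:
        raise ValueError("empty query")
    q_hit = coverage_fraction_overlap(query, annotation, coverage_frac, strict=strict)
    k, n = int(q_hit.sum()), len(query)

    if test == "hypergeometric":
        if genome_bins is None:
            raise ValueError("hypergeometric mode requires genome_bins")
        b_hit = coverage_fraction_overlap(genome_bins, annotation, coverage_frac, strict=strict)
        N, K = len(genome_bins), int(b_hit.sum())
        exp = K / N
        fc = (k / n) / exp if exp > 0 else np.inf
        p = hypergeom_upper_tail(k, N, K, n)
        return EnrichmentResult(k, n, k / n, exp, fc, _safe_log2(fc), p, "hypergeometric")

    if background is None:
        if layout is None:
            raise ValueError("fisher/log2fc modes need a background set or a layout")
        background = sample_matched_random_intervals(query, layout, exclude=exclude, seed=seed)
    b_hit = coverage_fraction_overlap(background, annotation, coverage_frac, strict=strict)
    kb, nb = int(b_hit.sum()), len(background)
    exp = kb / nb
    fc = (k / n) / exp if exp > 0 else np.inf
    if test == "fisher":
        p = fisher_exact_2x2([[k, n - k], [kb, nb - kb]])
        return EnrichmentResult(k, n, k / n, exp, fc, _safe_log2(fc), p, "fisher")
    if test == "log2fc":
        return EnrichmentResult(k, n, k / n, exp, fc, _safe_log2(fc), None, "log2fc")
    raise ValueError(f"unknown test {test!r}")


def _safe_log2(x: float) -> float:
    if x <= 0:
        return -np.inf
    return float(np.log2(x))
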