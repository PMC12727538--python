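"""Synthetic-data generators with known ground truth.

Three generators emulate the statistical structure of the study inputs so
every downstream stage is testable without external data:

* :func:`simulate_retainseq_counts` — window-level counts of an episome
  retention screen: lognormal window propensities, multiplicative enrichment
  of a spiked subset of windows compounding over time points, contiguous
  copy-number-gain background blocks, per-sample library sizes, dropout, and
  Poisson or negative-binomial counting noise. An expectation mode replaces
  every draw by its rounded mean so closed-form checks are exact.
* :func:`simulate_amplicon_catalog` — classified amplicon catalogs (ecDNA /
  BFB / linear) over an inhomogeneous retention-element landscape, with a
  configurable monotone link between local element density and ecDNA
  interval size (and no link for chromosomal classes).
* :func:`simulate_factor_peaks` — per-factor peak sets engineered to cover a
  target fraction of a query interval set unambiguously (each covering peak
  spans the full query interval).

All generators are deterministic given their seed and can round-trip their
outputs through TSV/BED plus a YAML config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .intervals import GenomeLayout, IntervalSet, bin_genome
from .retainseq import WindowCounts

__all__ = [
    "RetainSeqSimConfig",
    "AmpliconSimConfig",
    "PeakSimConfig",
    "simulate_retainseq_counts",
    "simulate_amplicon_catalog",
    "simulate_factor_peaks",
    "truth_for_windows",
]


def truth_for_windows(
    original: "IntervalSet", truth: np.ndarray, query: "IntervalSet"
) -> np.ndarray:
    """Align per-window truth labels with a (filtered) window subset.

    Matches windows by (chrom, start); raises if a query window is unknown.
    """
    key = {}
    for i, (c, s) in enumerate(zip(original.chroms, original.starts)):
        key[(c, int(s))] = bool(truth[i])
    out = np.empty(len(query), dtype=bool)
    for j, (c, s) in enumerate(zip(query.chroms, query.starts)):
        out[j] = key[(c, int(s))]
    return out


# ---------------------------------------------------------------------------
# Retain-seq screen counts


@dataclass
class RetainSeqSimConfig:
    """Study conditions of the synthetic retention screen.

    ``cn_blocks`` are (first window, one-past-last window, amplification
    factor) runs of background copy-number gain; blocks span >= 11 windows so
    the ±5 kb neighbour adjustment operates wholly inside a block.
    ``spike_effect`` multiplies a spiked window's expected output abundance
    per time step (compounding), emulating selective episome retention.
    """

    n_windows: int = 10_000
    n_replicates: int = 2
    n_timepoints: int = 3
    input_library_size: int = 2_000_000
    output_library_size: int = 2_000_000
    propensity_sigma: float = 1.0
    spike_fraction: float = 0.05
    spike_effect: float = 4.0
    cn_blocks: tuple[tuple[int, int, float], ...] | None = None
    dropout_rate: float = 0.0
    noise: str = "nb"  # "nb" | "poisson" | "none" (expectation mode)
    nb_dispersion: float = 0.1
    bin_size: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.spike_fraction < 1.0):
            raise ValueError("spike fraction must be in [0, 1)")
        if self.spike_effect <= 1.0:
            raise ValueError("spike effect must be > 1")
        if self.input_library_size <= 0 or self.output_library_size <= 0:
            raise ValueError("library sizes must be > 0")
        if self.noise not in ("nb", "poisson", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.cn_blocks is None:
            # default: one 8x gain block of >= 11 windows at 60% of the genome
            a = (self.n_windows * 6) // 10
            b = min(self.n_windows, a + max(11, self.n_windows // 100))
            self.cn_blocks = ((a, b, 8.0),) if b - a >= 11 else ()
        self.cn_blocks = tuple(tuple(blk) for blk in self.cn_blocks)
        for a, b, f in self.cn_blocks:
            if not (0 <= a < b <= self.n_windows) or f <= 0:
                raise ValueError(f"invalid copy-number block ({a}, {b}, {f})")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RetainSeqSimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cn_blocks" in raw:
            raw["cn_blocks"] = tuple(tuple(b) for b in raw["cn_blocks"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["cn_blocks"] = [list(b) for b in self.cn_blocks]
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _draw_counts(mean: np.ndarray, noise: str, dispersion: float,
                 rng: np.random.Generator) -> np.ndarray:
    if noise == "none":
        return np.rint(mean).astype(np.int64)
    if noise == "poisson":
        return rng.poisson(mean).astype(np.int64)
    # negative binomial with Var = m + dispersion * m^2
    n = 1.0 / dispersion
    m = np.maximum(mean, 1e-12)
    return rng.negative_binomial(n, n / (n + m)).astype(np.int64)


def simulate_retainseq_counts(
    config: RetainSeqSimConfig,
) -> tuple[WindowCounts, np.ndarray]:
    """Generate a windows × samples count table plus per-window truth labels.

    Input counts: noise-model draws around ``input_library_size * p_w / sum(p)``
    with lognormal propensities ``p_w``. Output counts at time index
    ``t = 1..T``: propensities scaled by ``spike_effect**t`` for spiked
    windows and by the block factor inside copy-number blocks, renormalised
    to the output library size. Truth labels mark the spiked windows.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    W = cfg.n_windows

    p = np.exp(rng.normal(0.0, cfg.propensity_sigma, size=W))
    spiked = np.zeros(W, dtype=bool)
    n_spike = int(round(cfg.spike_fraction * W))
    if n_spike:
        spiked[rng.choice(W, size=n_spike, replace=False)] = True

    cn_factor = np.ones(W)
    for a, b, f in cfg.cn_blocks:
        cn_factor[a:b] = f

    # synthetic layout: two chromosomes, 60/40 split, 1-kb windows
    w1 = (W * 6) // 10
    layout = GenomeLayout(
        ("chrS1", "chrS2"), (w1 * cfg.bin_size, (W - w1) * cfg.bin_size)
    )
    windows = bin_genome(layout, cfg.bin_size)
    assert len(windows) == W

    sample_rows = [{"sample": "input", "role": "input", "replicate": 0, "timepoint": 0}]
    columns = {"input": _draw_counts(
        cfg.input_library_size * p / p.sum(), cfg.noise, cfg.nb_dispersion, rng
    )}
    for t in range(1, cfg.n_timepoints + 1):
        effect = np.where(spiked, cfg.spike_effect ** t, 1.0)
        q = p * effect * cn_factor
        mean = cfg.output_library_size * q / q.sum()
        for r in range(1, cfg.n_replicates + 1):
            name = f"out_t{t}_r{r}"
            counts = _draw_counts(mean, cfg.noise, cfg.nb_dispersion, rng)
            if cfg.dropout_rate > 0:
                counts[rng.random(W) < cfg.dropout_rate] = 0
            columns[name] = counts
            sample_rows.append(
                {"sample": name, "role": "output", "replicate": r, "timepoint": t}
            )
    counts_df = pd.DataFrame(columns)
    samples = pd.DataFrame(sample_rows).set_index("sample")
    return WindowCounts(windows, counts_df, samples), spiked


# ---------------------------------------------------------------------------
# amplicon catalogs over an inhomogeneous element landscape


def _default_layout() -> GenomeLayout:
    return GenomeLayout.from_dict(
        {"chrA": 60_000_000, "chrB": 60_000_000, "chrC": 60_000_000, "chrD": 60_000_000}
    )


@dataclass
class AmpliconSimConfig:
    """Conditions for synthetic classified amplicon catalogs.

    Retention elements are placed by a hotspot mixture (a fraction
    ``hotspot_weight`` of elements cluster around Gaussian hotspots, the rest
    uniform), giving an inhomogeneous local density. For the ecDNA class,
    log interval width decreases linearly with the standardised local density
    at the interval anchor with slope ``density_link`` (0 = null catalog);
    BFB/linear widths are density-independent.
    """

    layout: GenomeLayout = field(default_factory=_default_layout)
    n_elements: int = 3000
    element_width: int = 1000
    n_hotspots: int = 40
    hotspot_sd: float = 1.5e6
    hotspot_weight: float = 0.8
    class_counts: dict = field(
        default_factory=lambda: {"ecDNA": 500, "BFB": 200, "linear": 500}
    )
    log10_width_mean: dict = field(
        default_factory=lambda: {"ecDNA": 6.0, "BFB": 6.0, "linear": 5.5}
    )
    log10_width_sd: float = 0.35
    density_link: float = 0.3
    half_window: float = 2.5e6
    multi_interval_prob: float = 0.3
    n_oncogenes: int = 30
    oncogene_width: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not set(self.class_counts) <= {"ecDNA", "BFB", "linear"}:
            raise ValueError("classes must be within {ecDNA, BFB, linear}")
        if self.element_width <= 0 or self.oncogene_width <= 0:
            raise ValueError("widths must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AmpliconSimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "layout" in raw:
            raw["layout"] = GenomeLayout.from_dict(raw["layout"])
        return cls(**raw)


def _place_elements(cfg: AmpliconSimConfig, rng: np.random.Generator) -> IntervalSet:
    lengths = np.asarray(cfg.layout.lengths, dtype=float)
    chrom_p = lengths / lengths.sum()
    hot_chrom = rng.choice(len(lengths), size=cfg.n_hotspots, p=chrom_p)
    hot_pos = rng.random(cfg.n_hotspots) * lengths[hot_chrom]
    records = []
    for _ in range(cfg.n_elements):
        if rng.random() < cfg.hotspot_weight:
            h = rng.integers(cfg.n_hotspots)
            ci = int(hot_chrom[h])
            mid = int(np.clip(rng.normal(hot_pos[h], cfg.hotspot_sd), 0,
                              lengths[ci] - 1))
        else:
            ci = int(rng.choice(len(lengths), p=chrom_p))
            mid = int(rng.random() * lengths[ci])
        half = cfg.element_width // 2
        start = int(np.clip(mid - half, 0, lengths[ci] - cfg.element_width))
        records.append((cfg.layout.names[ci], start, start + cfg.element_width))
    iset = IntervalSet.from_records(records)
    return IntervalSet(iset.df.sort_values(["chrom", "start"]).reset_index(drop=True))


def _local_density(mids_by_chrom: dict[str, np.ndarray], chrom: str, pos: float,
                   half_window: float) -> float:
    mids = mids_by_chrom.get(chrom)
    if mids is None:
        return 0.0
    lo = np.searchsorted(mids, pos - half_window)
    hi = np.searchsorted(mids, pos + half_window)
    return (hi - lo) / (2 * half_window / 1e6)  # per Mb


def simulate_amplicon_catalog(
    config: AmpliconSimConfig,
) -> tuple[pd.DataFrame, IntervalSet, IntervalSet]:
    """Generate (amplicon interval catalog, retention elements, oncogenes).

    The catalog has columns ``sample, amplicon_id, class, chrom, start, end``
    plus generator truth columns ``anchor_density`` (local element density at
    the anchor, per Mb) and ``is_primary``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    elements = _place_elements(cfg, rng)
    mids_by_chrom = {
        str(c): np.sort(sub["start"].to_numpy() + cfg.element_width // 2)
        for c, sub in elements.df.groupby("chrom")
    }
    lengths = np.asarray(cfg.layout.lengths, dtype=float)
    chrom_p = lengths / lengths.sum()

    # standardise density against its genome-wide distribution
    probe_ci = rng.choice(len(lengths), size=2000, p=chrom_p)
    probe_pos = rng.random(2000) * lengths[probe_ci]
    probe_d = np.array(
        [
            _local_density(mids_by_chrom, cfg.layout.names[ci], pos, cfg.half_window)
            for ci, pos in zip(probe_ci, probe_pos)
        ]
    )
    d_mean, d_sd = probe_d.mean(), max(probe_d.std(), 1e-9)

    rows = []
    amp_counter = 0
    for klass, n_amp in cfg.class_counts.items():
        link = cfg.density_link if klass == "ecDNA" else 0.0
        for _ in range(n_amp):
            amp_counter += 1
            amp_id = f"amp{amp_counter:05d}"
            sample = f"S{amp_counter:05d}"
            n_intervals = 1 + (rng.random() < cfg.multi_interval_prob)
            for ii in range(n_intervals):
                ci = int(rng.choice(len(lengths), p=chrom_p))
                chrom = cfg.layout.names[ci]
                mid = rng.random() * lengths[ci]
                d = _local_density(mids_by_chrom, chrom, mid, cfg.half_window)
                z = (d - d_mean) / d_sd
                mu = cfg.log10_width_mean[klass] if ii == 0 else cfg.log10_width_mean[klass] - 0.5
                lw = rng.normal(mu, cfg.log10_width_sd) - (link * z if ii == 0 else 0.0)
                width = int(np.clip(10 ** lw, 10_000, lengths[ci] - 1))
                start = int(np.clip(mid - width / 2, 0, lengths[ci] - width))
                rows.append(
                    {
                        "sample": sample,
                        "amplicon_id": amp_id,
                        "class": klass,
                        "chrom": chrom,
                        "start": start,
                        "end": start + width,
                        "anchor_density": d,
                        "is_primary": ii == 0,
                    }
                )
    catalog = pd.DataFrame(rows)

    onc_records, onc_names = [], []
    for i in range(cfg.n_oncogenes):
        ci = int(rng.choice(len(lengths), p=chrom_p))
        start = int(rng.random() * (lengths[ci] - cfg.oncogene_width))
        onc_records.append((cfg.layout.names[ci], start, start + cfg.oncogene_width))
        onc_names.append(f"ONC{i + 1}")
    oncogenes = IntervalSet.from_records(onc_records, names=onc_names)
    return catalog, elements, oncogenes


# ---------------------------------------------------------------------------
# factor peak collections


@dataclass
class PeakSimConfig:
    """Per-factor target coverage of a query interval set.

    ``coverages`` maps factor name -> fraction of query intervals that the
    factor's peaks must cover (each covering peak spans the whole interval,
    so any downstream >=50% coverage call is unambiguous). ``nested=True``
    draws covered subsets as prefixes of one fixed random permutation, so a
    lower-coverage factor's covered set is contained in every
    higher-coverage factor's set. Background peaks are placed uniformly on
    the layout (they may incidentally hit query intervals only if
    ``background_avoid_query`` is disabled).
    """

    coverages: dict = field(default_factory=dict)
    nested: bool = False
    layout: GenomeLayout | None = None
    background_peaks: int = 0
    background_width: int = 500
    background_avoid_query: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name, c in self.coverages.items():
            if not (0.0 <= c <= 1.0):
                raise ValueError(f"coverage target for {name!r} outside [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PeakSimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "layout" in raw and raw["layout"] is not None:
            raw["layout"] = GenomeLayout.from_dict(raw["layout"])
        return cls(**raw)


def simulate_factor_peaks(
    config: PeakSimConfig, query: IntervalSet
) -> dict[str, IntervalSet]:
    """Generate one peak IntervalSet per factor hitting its coverage target."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = len(query)
    order = rng.permutation(n)
    out: dict[str, IntervalSet] = {}
    qdf = query.df
    for name, cov in cfg.coverages.items():
        k = int(round(cov * n))
        chosen = order[:k] if cfg.nested else rng.choice(n, size=k, replace=False)
        frames = [qdf.iloc[np.sort(chosen)][["chrom", "start", "end"]]]
        if cfg.background_peaks and cfg.layout is not None:
            from .intervals import sample_matched_random_intervals

            template = IntervalSet.from_records(
                [("bg", 0, cfg.background_width)] * cfg.background_peaks
            )
            bg = sample_matched_random_intervals(
                template,
                cfg.layout,
                exclude=query if cfg.background_avoid_query else None,
                seed=rng,
            )
            frames.append(bg.df)
        out[name] = IntervalSet(pd.concat(frames, ignore_index=True))
    return out
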