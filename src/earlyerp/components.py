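"""ERP component machinery: averaging, occurrence criterion, peaks, windows
of interest, mean-amplitude and peak-to-peak quantification.

The occurrence criterion for the very early negative deflection is
deliberately liberal (low SNR): a component is declared present in a
condition's averaged waveform when at least two *neighboring* posterior
channels each show at least two consecutive samples beyond +/-1.5 baseline
standard deviations inside the search window.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EpochSet
from .layout import ChannelLayout, build_adjacency  # re-exported surface

__all__ = [
    "ComponentSpec",
    "DetectionCriterion",
    "DetectionResult",
    "WOI",
    "AverageSet",
    "build_adjacency",
    "grand_average",
    "detect_component",
    "meta_average",
    "find_peak",
    "make_woi",
    "mean_amplitude",
    "peak_to_peak",
    "default_meta_electrodes",
]

#: WOI half-widths (ms) by polarity, as used for all printed windows
HALF_WIDTH_NEG = 3.0
HALF_WIDTH_POS = 6.0


@dataclass(frozen=True)
class ComponentSpec:
    """A named deflection: polarity, search window and WOI half-width."""

    name: str
    polarity: str  # 'negative' | 'positive'
    search_window: tuple[float, float]
    woi_half_width: float | None = None

    def __post_init__(self):
        if self.polarity not in ("negative", "positive"):
            raise ValueError("polarity must be 'negative' or 'positive'")
        if self.search_window[0] >= self.search_window[1]:
            raise ValueError("empty search window")
        if self.woi_half_width is None:
            object.__setattr__(
                self,
                "woi_half_width",
                HALF_WIDTH_NEG if self.polarity == "negative" else HALF_WIDTH_POS,
            )
        if self.woi_half_width <= 0:
            raise ValueError("half width must be positive")


@dataclass(frozen=True)
class DetectionCriterion:
    """Occurrence rule parameters (all counts >= 1)."""

    sd_mult: float = 1.5
    min_channels: int = 2
    min_consecutive_samples: int = 2
    polarity_restricted: bool = False
    require_overlap: bool = False

    def __post_init__(self):
        if self.min_channels < 1 or self.min_consecutive_samples < 1:
            raise ValueError("counts must be >= 1")


@dataclass(frozen=True)
class WOI:
    """Window of interest centered on a component's meta-average peak."""

    component: str
    peak_latency: float
    lo: float
    hi: float


@dataclass(frozen=True)
class DetectionResult:
    detected: bool
    qualifying_channels: tuple[str, ...]
    runs: dict  # channel name -> list of (start_ms, end_ms) supra-threshold runs


@dataclass
class AverageSet:
    """Per-participant and grand condition averages.

    ``participant_averages`` maps (participant, category, location) to a
    channels x samples waveform (kept trials only); ``grand`` maps
    (category, location) to the unweighted across-participant mean.
    """

    participant_averages: dict
    grand: dict
    times: np.ndarray
    channel_names: list[str]

    def conditions(self) -> list[tuple[str, str]]:
        return sorted(self.grand.keys())

    def participants(self) -> list:
        return sorted({p for (p, _, _) in self.participant_averages})


def grand_average(es: EpochSet, scalp_names: list[str] | None = None) -> AverageSet:
    """Average kept trials per participant x condition, then across participants."""
    if scalp_names is None:
        aux = {"Nose", "VEOG", "HEOG"}
        scalp_names = [c for c in es.channel_names if c not in aux]
    ch_idx = es.scalp_indices(scalp_names)
    meta = es.metadata
    kept = meta["kept"].to_numpy().astype(bool)
    part_avgs: dict = {}
    for (p, cat, loc), rows in meta.groupby(["participant", "category", "location"], observed=True):
        sel = rows.index.to_numpy()[kept[rows.index.to_numpy()]]
        if len(sel) == 0:
            raise ValueError(f"empty cell: participant {p}, {cat}/{loc}")
        part_avgs[(p, cat, loc)] = es.data[np.ix_(sel, ch_idx)].mean(axis=0)
    grand: dict = {}
    conds = sorted({(c, l) for (_, c, l) in part_avgs})
    for cat, loc in conds:
        stack = [w for (p, c, l), w in part_avgs.items() if (c, l) == (cat, loc)]
        grand[(cat, loc)] = np.mean(stack, axis=0)
    return AverageSet(
        participant_averages=part_avgs,
        grand=grand,
        times=es.times.copy(),
        channel_names=list(scalp_names),
    )


def _supra_runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Index runs of at least min_len consecutive True values."""
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            if i - start >= min_len:
                runs.append((start, i - 1))
            start = None
    if start is not None and len(mask) - start >= min_len:
        runs.append((start, len(mask) - 1))
    return runs


def detect_component(
    cond_avg: np.ndarray,
    times: np.ndarray,
    spec: ComponentSpec,
    crit: DetectionCriterion,
    adjacency: np.ndarray,
    layout: ChannelLayout,
    region_mask: np.ndarray | None = None,
) -> DetectionResult:
    """Apply the occurrence criterion to one condition's averaged waveform.

    Per channel the threshold is ``sd_mult`` times the SD of that channel's
    own baseline (t < 0) samples of the same average. A channel qualifies
    if it shows >= ``min_consecutive_samples`` consecutive samples inside
    the search window beyond the threshold (either polarity by default).
    Detection requires >= ``min_channels`` qualifying channels that are
    mutually adjacent within the posterior region.
    """
    if region_mask is None:
        region_mask = layout.posterior_mask()
    region_idx = np.flatnonzero(region_mask)
    if len(region_idx) == 0:
        raise ValueError("empty detection region")
    base = times < 0
    if not base.any():
        raise ValueError("no baseline samples available")
    win = (times >= spec.search_window[0]) & (times <= spec.search_window[1])

    qual: list[int] = []
    runs: dict = {}
    run_spans: dict = {}
    for ci in region_idx:
        thr = crit.sd_mult * cond_avg[ci, base].std()
        x = cond_avg[ci, win]
        if crit.polarity_restricted:
            supra = (x < -thr) if spec.polarity == "negative" else (x > thr)
        else:
            supra = np.abs(x) > thr
        r = _supra_runs(supra, crit.min_consecutive_samples)
        if r:
            qual.append(ci)
            tw = times[win]
            runs[layout.names[ci]] = [(float(tw[a]), float(tw[b])) for a, b in r]
            run_spans[ci] = r

    detected = False
    if len(qual) >= crit.min_channels:
        for i, a in enumerate(qual):
            for b in qual[i + 1 :]:
                if not adjacency[a, b]:
                    continue
                if crit.require_overlap:
                    ok = any(
                        max(ra[0], rb[0]) <= min(ra[1], rb[1])
                        for ra in run_spans[a]
                        for rb in run_spans[b]
                    )
                    if not ok:
                        continue
                detected = True
                break
            if detected:
                break

    return DetectionResult(
        detected=detected,
        qualifying_channels=tuple(layout.names[i] for i in qual),
        runs=runs,
    )


def default_meta_electrodes(layout: ChannelLayout, laterality: str = "bilateral") -> list[str]:
    """Parietal/occipital electrode set for meta-averaging.

    'bilateral' returns the full posterior row set; 'left'/'right' restrict
    to one hemisphere plus the midline (contralateral sets for peripheral
    stimuli are the mirror of the bilateral set on the opposite side).
    """
    mask = layout.posterior_mask() & layout.laterality_mask(laterality)
    return [n for n, m in zip(layout.names, mask) if m]


def meta_average(
    grand: dict,
    layout: ChannelLayout,
    channel_names: list[str],
    electrodes: list[str],
    location: str,
) -> np.ndarray:
    """Mean waveform over an electrode set and over both categories."""
    if not electrodes:
        raise ValueError("empty electrode set")
    idx = []
    for e in electrodes:
        if e not in channel_names:
            raise KeyError(f"unknown electrode {e!r}")
        idx.append(channel_names.index(e))
    waves = [w[idx].mean(axis=0) for (cat, loc), w in grand.items() if loc == location]
    if not waves:
        raise ValueError(f"no conditions at location {location!r}")
    return np.mean(waves, axis=0)


def find_peak(meta: np.ndarray, times: np.ndarray, spec: ComponentSpec) -> float:
    """Latency (ms) of the polarity-matched extremum inside the search window.

    Ties resolve to the earliest latency.
    """
    win = (times >= spec.search_window[0]) & (times <= spec.search_window[1])
    if not win.any():
        raise ValueError("search window outside the epoch")
    x = meta[win]
    tw = times[win]
    i = int(np.argmin(x)) if spec.polarity == "negative" else int(np.argmax(x))
    return float(tw[i])


def make_woi(peak: float, spec: ComponentSpec) -> WOI:
    """Window of interest: peak +/- half-width (3 ms negative, 6 ms positive)."""
    h = spec.woi_half_width
    return WOI(component=spec.name, peak_latency=float(peak), lo=float(peak - h), hi=float(peak + h))


def mean_amplitude(avgs: AverageSet, woi: WOI, location: str) -> pd.DataFrame:
    """Mean voltage within the WOI per participant x condition x channel.

    Returns a DataFrame indexed by (participant, category) with one column
    per channel; closed interval [lo, hi] on the nominal time axis.
    """
    sel = (avgs.times >= woi.lo) & (avgs.times <= woi.hi)
    if not sel.any():
        raise ValueError("WOI contains no samples")
    rows = {}
    for (p, cat, loc), w in avgs.participant_averages.items():
        if loc != location:
            continue
        rows[(p, cat)] = w[:, sel].mean(axis=1)
    if not rows:
        raise ValueError(f"no averages at location {location!r}")
    df = pd.DataFrame.from_dict(rows, orient="index", columns=avgs.channel_names)
    df.index = pd.MultiIndex.from_tuples(df.index, names=["participant", "category"])
    return df.sort_index()


def peak_to_peak(pos_table: pd.DataFrame, neg_table: pd.DataFrame) -> pd.DataFrame:
    """Element-wise positive-component minus negative-component amplitude."""
    if not pos_table.index.equals(neg_table.index) or not pos_table.columns.equals(
        neg_table.columns
    ):
        raise ValueError("amplitude tables are misaligned")
    return pos_table - neg_table
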