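"""Sliding-window genomic profiling and comparison to occupancy tracks.

A profile applies one measure to every 147-nt window (nucleosomal DNA
length) of a sequence; occupancy tracks are per-position values read from
plain-text formats (two-column TSV, bedGraph, fixed-step wiggle).  Profiles
and tracks are compared by Spearman rank correlation, either globally or on
a sliding correlation window.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import stats

from .measures import MeasureSpec, compute
from .transforms import SymbolSequence

__all__ = [
    "Profile",
    "OccupancyTrack",
    "profile",
    "normalize01",
    "decimate",
    "spearman",
    "windowed_correlation",
    "read_track_tsv",
    "read_bedgraph",
    "read_wiggle",
    "write_profile",
]

NUCLEOSOME_WINDOW = 147


@dataclass
class Profile:
    """Per-window score series; ``values[j]`` belongs to the window starting
    at coordinate ``start + j * step`` (0-based, source coordinates).
    Missing scores (windows touching invalid symbols) are NaN."""

    values: np.ndarray
    name: str
    start: int
    window: int
    step: int
    spec: MeasureSpec | None = field(default=None, repr=False)
    spec_label: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.spec is not None and not self.spec_label:
            self.spec_label = self.spec.label()

    def __len__(self) -> int:
        return len(self.values)

    def window_starts(self) -> np.ndarray:
        return self.start + self.step * np.arange(len(self.values))

    def window_centers(self) -> np.ndarray:
        return self.window_starts() + self.window // 2


@dataclass
class OccupancyTrack:
    """Dense per-position occupancy values for one region.

    ``values[i]`` is the occupancy at coordinate ``start + i``; ``source``
    labels where the track came from (in vivo / in vitro / model /
    synthetic)."""

    values: np.ndarray
    name: str = ""
    start: int = 0
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


def profile(
    seq: SymbolSequence,
    spec: MeasureSpec,
    window: int = NUCLEOSOME_WINDOW,
    step: int = 1,
) -> Profile:
    """Score every length-``window`` substring of ``seq`` with ``spec``.

    Windows containing out-of-alphabet symbols yield NaN.  The number of
    values is ``floor((L - window) / step) + 1``.
    """
    if window < 1 or window > len(seq):
        raise ValueError(f"window {window} invalid for sequence of length {len(seq)}")
    if step < 1:
        raise ValueError("step must be >= 1")
    valid = seq.valid_mask()
    # a window is scoreable iff it contains no invalid position
    bad_cum = np.concatenate([[0], np.cumsum(~valid)])
    n_windows = (len(seq) - window) // step + 1
    values = np.full(n_windows, np.nan)
    for j in range(n_windows):
        s = j * step
        if bad_cum[s + window] - bad_cum[s] > 0:
            continue
        values[j] = compute(seq.subsequence(s, s + window), spec)
    return Profile(
        values=values,
        name=seq.name,
        start=seq.origin_offset,
        window=window,
        step=step,
        spec=spec,
    )


def normalize01(p: Profile) -> Profile:
    """Rescale non-missing values onto [0, 1] (rank-preserving).

    A constant profile maps to all 0.5 with a warning, so downstream
    extremum calling sees an explicitly uninformative series.
    """
    v = p.values.copy()
    finite = np.isfinite(v)
    if not finite.any():
        return replace(p, values=v, normalized=True)
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi == lo:
        warnings.warn("constant profile; normalized to all 0.5", stacklevel=2)
        v[finite] = 0.5
    else:
        v[finite] = (v[finite] - lo) / (hi - lo)
    return replace(p, values=v, normalized=True)


def decimate(p: Profile, every: int = 10) -> Profile:
    """Keep every ``every``-th value starting at index 0 (simple smoothing
    by subsampling); the effective step is multiplied accordingly."""
    if every < 1:
        raise ValueError("every must be >= 1")
    return replace(p, values=p.values[::every].copy(), step=p.step * every)


def _aligned_pairs(
    p: Profile,
    t: OccupancyTrack,
    alignment: str = "window-center",
    footprint_mean: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair each window score with its occupancy value.

    By default occupancy is averaged over the window footprint (a window
    score describes 147 nt, so it is compared with the mean occupancy of
    those 147 nt); with ``footprint_mean=False`` the single track value at
    the window centre (or start) is used instead.
    """
    if alignment not in ("window-center", "window-start"):
        raise ValueError(f"unknown alignment {alignment!r}")
    starts = p.window_starts() - t.start
    scores = p.values
    occ = np.full(len(scores), np.nan)
    tv = t.values
    if footprint_mean:
        cs = np.concatenate([[0.0], np.nancumsum(tv)])
        cnt = np.concatenate([[0], np.cumsum(np.isfinite(tv))])
        for j, s in enumerate(starts):
            e = s + p.window
            if s < 0 or e > len(tv):
                continue
            n = cnt[e] - cnt[s]
            if n > 0:
                occ[j] = (cs[e] - cs[s]) / n
    else:
        pos = starts + (p.window // 2 if alignment == "window-center" else 0)
        ok = (pos >= 0) & (pos < len(tv))
        occ[ok] = tv[pos[ok]]
    return scores, occ


def spearman(
    p: Profile,
    t: OccupancyTrack,
    alignment: str = "window-center",
    footprint_mean: bool = True,
) -> float:
    """Spearman rank correlation between a profile and an occupancy track.

    Average ranks on ties; pairs with a missing member are dropped; at
    least 3 complete pairs are required.
    """
    scores, occ = _aligned_pairs(p, t, alignment, footprint_mean)
    ok = np.isfinite(scores) & np.isfinite(occ)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 aligned non-missing pairs")
    return float(stats.spearmanr(scores[ok], occ[ok]).statistic)


@dataclass
class WindowedCorrelation:
    """Sliding-window Spearman correlations plus their extremes."""

    correlations: Profile
    max_correlation: float
    min_correlation: float


def windowed_correlation(
    p: Profile,
    t: OccupancyTrack,
    corr_window: int = 4000,
    corr_step: int = 1,
    alignment: str = "window-center",
    footprint_mean: bool = True,
) -> WindowedCorrelation:
    """Spearman correlation on a correlation window slid along the pair.

    ``corr_window`` counts profile points (at step 1, nucleotides).  The
    max-min spread over the track is how locally variable the agreement
    between a measure and the occupancy is.
    """
    scores, occ = _aligned_pairs(p, t, alignment, footprint_mean)
    if corr_window < 3 or corr_window > len(scores):
        raise ValueError("corr_window must be in [3, number of profile points]")
    n = (len(scores) - corr_window) // corr_step + 1
    cors = np.full(n, np.nan)
    for j in range(n):
        s = j * corr_step
        xs = scores[s : s + corr_window]
        ys = occ[s : s + corr_window]
        ok = np.isfinite(xs) & np.isfinite(ys)
        if ok.sum() >= 3 and len(np.unique(xs[ok])) > 1 and len(np.unique(ys[ok])) > 1:
            cors[j] = stats.spearmanr(xs[ok], ys[ok]).statistic
    prof = Profile(
        values=cors,
        name=p.name,
        start=p.start,
        window=corr_window,
        step=p.step * corr_step,
        spec_label=f"spearman[{p.spec_label}]",
    )
    finite = cors[np.isfinite(cors)]
    if len(finite) == 0:
        raise ValueError("no correlation window had enough complete pairs")
    return WindowedCorrelation(prof, float(finite.max()), float(finite.min()))


# ---------------------------------------------------------------------------
# Track and profile I/O
# ---------------------------------------------------------------------------

def read_track_tsv(path: str | Path, name: str = "", source: str = "synthetic") -> OccupancyTrack:
    """Two-column TSV: 1-based position, value.  Gaps become NaN."""
    positions, values = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track")):
            continue
        pos_s, val_s = line.split("\t")[:2]
        positions.append(int(pos_s) - 1)
        values.append(float(val_s))
    if not positions:
        raise ValueError(f"{path}: empty track")
    start = min(positions)
    arr = np.full(max(positions) - start + 1, np.nan)
    for pos, val in zip(positions, values):
        arr[pos - start] = val
    return OccupancyTrack(arr, name, start, source)


def read_bedgraph(path: str | Path, source: str = "synthetic") -> OccupancyTrack:
    """bedGraph (chrom, 0-based half-open start/end, value), one chromosome."""
    chrom = None
    spans: list[tuple[int, int, float]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        c, s, e, v = line.split("\t")[:4]
        if chrom is None:
            chrom = c
        elif c != chrom:
            raise ValueError(f"{path}: multiple chromosomes ({chrom}, {c})")
        spans.append((int(s), int(e), float(v)))
    if not spans:
        raise ValueError(f"{path}: empty bedGraph")
    start = min(s for s, _, _ in spans)
    end = max(e for _, e, _ in spans)
    arr = np.full(end - start, np.nan)
    for s, e, v in spans:
        arr[s - start : e - start] = v
    return OccupancyTrack(arr, chrom or "", start, source)


def read_wiggle(path: str | Path, source: str = "synthetic") -> OccupancyTrack:
    """Fixed-step wiggle (``fixedStep chrom=... start=... step=...``, 1-based)."""
    chrom, start, step, span = None, None, 1, 1
    chunks: list[tuple[int, list[float]]] = []
    current: list[float] | None = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track")):
            continue
        if line.startswith("fixedStep"):
            fields = dict(kv.split("=") for kv in line.split()[1:])
            chrom = fields["chrom"]
            start = int(fields["start"]) - 1
            step = int(fields.get("step", 1))
            span = int(fields.get("span", 1))
            current = []
            chunks.append((start, current))
            continue
        if current is None:
            raise ValueError(f"{path}: data before fixedStep header")
        current.append(float(line))
    if not chunks:
        raise ValueError(f"{path}: no fixedStep blocks")
    lo = min(s for s, _ in chunks)
    hi = max(s + step * (len(vals) - 1) + span for s, vals in chunks)
    arr = np.full(hi - lo, np.nan)
    for s, vals in chunks:
        for i, v in enumerate(vals):
            pos = s + i * step - lo
            arr[pos : pos + span] = v
    return OccupancyTrack(arr, chrom or "", lo, source)


def write_profile(p: Profile, path: str | Path) -> None:
    """Write a profile as bedGraph-style TSV plus a JSON metadata sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        name = p.name or "region"
        for j, v in enumerate(p.values):
            s = p.start + j * p.step
            val = "nan" if not np.isfinite(v) else repr(float(v))
            fh.write(f"{name}\t{s}\t{s + p.step}\t{val}\n")
    meta = {
        "name": p.name,
        "start": p.start,
        "window": p.window,
        "step": p.step,
        "measure": p.spec_label,
        "normalized": p.normalized,
        "n_values": len(p.values),
    }
    if p.spec is not None:
        meta["k"] = p.spec.k
        meta["block_len"] = p.spec.block_len
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
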