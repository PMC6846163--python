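"""Wedge dinucleotide model of intrinsic DNA curvature.

The wedge model attributes DNA bending to a fixed angular deflection
driven between adjacent base pairs at specific dinucleotide steps — in the
minimal parameterization, 8.7 degrees for each AA step and nothing else.
Successive wedges act at the helical phase of their step (34.3 degrees of
twist per step, one turn per ~10.5 bp), so wedges spaced at the helical
period add coherently (phased A-tracts bend DNA macroscopically) while
wedges at half-period spacing cancel.

A window's bend magnitude is the norm of the planar resultant

    | sum_j  w(step_j) * exp(i * twist * j) |

over the dinucleotide steps of the window, in degrees.  Because a shift of
the window only rotates every term by a common phase, the magnitude depends
on AA phasing alone, not on absolute position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .measures import MeasureSpec, compute
from .tm_engine import CTMTable
from .transforms import DNA, SymbolSequence

__all__ = [
    "WedgeParameters",
    "predict_curvature",
    "axis_trajectory",
    "curvature_vs_complexity",
    "read_wedge_table",
]

DINUCLEOTIDES = tuple(a + b for a in DNA for b in DNA)


@dataclass(frozen=True)
class WedgeParameters:
    """Wedge angles per dinucleotide step plus the helical twist.

    Defaults carry the single-parameter model (AA = 8.7 degrees, all other
    steps flat, twist 34.3 degrees/step).  ``include_tt_as_aa`` optionally
    reads TT steps as AA seen from the opposite strand.
    """

    wedge_deg: dict = field(default_factory=lambda: {"AA": 8.7})
    twist_deg_per_step: float = 34.3
    include_tt_as_aa: bool = False

    def __post_init__(self) -> None:
        bad = set(self.wedge_deg) - set(DINUCLEOTIDES)
        if bad:
            raise ValueError(f"unknown dinucleotides in wedge table: {sorted(bad)}")
        if not all(np.isfinite(v) for v in self.wedge_deg.values()):
            raise ValueError("wedge angles must be finite")

    def effective_wedges(self) -> dict:
        wedges = dict(self.wedge_deg)
        if self.include_tt_as_aa and "AA" in wedges:
            wedges.setdefault("TT", wedges["AA"])
        return wedges


def _step_wedges(seq: SymbolSequence, params: WedgeParameters) -> np.ndarray:
    """Per-step wedge magnitudes (degrees); NaN where a base is masked."""
    wedges = params.effective_wedges()
    s = seq.symbols
    valid = seq.valid_mask()
    out = np.zeros(len(s) - 1)
    for i in range(len(s) - 1):
        if not (valid[i] and valid[i + 1]):
            out[i] = np.nan
        else:
            out[i] = wedges.get(s[i : i + 2], 0.0)
    return out


def predict_curvature(
    seq: SymbolSequence,
    params: WedgeParameters | None = None,
    window: int = 147,
) -> np.ndarray:
    """Bend magnitude (degrees) per sliding window of ``window`` nt.

    ``values[j]`` is the planar resultant norm over the dinucleotide steps
    of the window starting at ``j``; windows touching a masked base are
    NaN.  Zero when no wedged dinucleotide occurs in the window.
    """
    if params is None:
        params = WedgeParameters()
    if window < 2 or window > len(seq):
        raise ValueError(f"window {window} invalid for sequence of length {len(seq)}")
    w = _step_wedges(seq, params)
    phase = np.deg2rad(params.twist_deg_per_step) * np.arange(len(w))
    terms = w * np.exp(1j * phase)
    n_steps = window - 1
    n_windows = len(seq) - window + 1
    # sliding sums via cumulative sums; NaN propagates through windows
    csum = np.concatenate([[0.0 + 0.0j], np.cumsum(np.where(np.isnan(w), 0, terms))])
    bad = np.concatenate([[0], np.cumsum(np.isnan(w).astype(int))])
    out = np.empty(n_windows)
    for j in range(n_windows):
        if bad[j + n_steps] - bad[j] > 0:
            out[j] = np.nan
        else:
            out[j] = abs(csum[j + n_steps] - csum[j])
    return out


def axis_trajectory(
    seq: SymbolSequence, params: WedgeParameters | None = None, rise: float = 3.4
) -> np.ndarray:
    """Approximate 3D path of the helical axis, one point per base pair.

    The axis advances ``rise`` angstroms per step along its local tangent;
    at each wedged step the tangent is deflected by the wedge angle in the
    direction set by the accumulated helical twist.  Returns an (L, 3)
    coordinate array.  This is the minimal rigid-wedge geometry, adequate
    for visual comparison of phased versus unphased A-tracts.
    """
    if params is None:
        params = WedgeParameters()
    w = _step_wedges(seq, params)
    twist = np.deg2rad(params.twist_deg_per_step)
    points = np.zeros((len(seq), 3))
    tangent = np.array([0.0, 0.0, 1.0])
    normal = np.array([1.0, 0.0, 0.0])
    binormal = np.array([0.0, 1.0, 0.0])
    pos = np.zeros(3)
    for i, wedge in enumerate(w):
        phi = i * twist
        angle = 0.0 if np.isnan(wedge) else np.deg2rad(wedge)
        if angle != 0.0:
            axis = np.cos(phi) * normal + np.sin(phi) * binormal
            tangent = _rotate(tangent, axis, angle)
            normal = _rotate(normal, axis, angle)
            binormal = np.cross(tangent, normal)
        pos = pos + rise * tangent
        points[i + 1] = pos
    return points


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about unit ``axis`` by ``angle``."""
    axis = axis / np.linalg.norm(axis)
    return (
        v * np.cos(angle)
        + np.cross(axis, v) * np.sin(angle)
        + axis * np.dot(axis, v) * (1 - np.cos(angle))
    )


def sequence_curvature(
    seq: SymbolSequence, params: WedgeParameters | None = None, window: int = 147
) -> float:
    """Scalar curvature of one sequence: mean window bend magnitude.

    Sequences shorter than ``window`` are scored as a single window of
    their own length.
    """
    w = min(window, len(seq))
    vals = predict_curvature(seq, params, w)
    finite = vals[np.isfinite(vals)]
    return float(finite.mean()) if len(finite) else float("nan")


def curvature_vs_complexity(
    seqs: list[SymbolSequence],
    specs: list[MeasureSpec],
    params: WedgeParameters | None = None,
    window: int = 147,
) -> pd.DataFrame:
    """Spearman correlation of modelled curvature against each measure.

    One curvature value and one score per sequence per measure; constant
    inputs give NaN (reported as missing, never fabricated).  Returns a
    DataFrame indexed by measure label with columns ``rho`` and ``n``.
    """
    from scipy import stats

    curv = np.array([sequence_curvature(s, params, window) for s in seqs])
    rows = []
    for spec in specs:
        scores = np.array([compute(s, spec) for s in seqs])
        ok = np.isfinite(curv) & np.isfinite(scores)
        if ok.sum() < 3 or len(set(curv[ok])) < 2 or len(set(scores[ok])) < 2:
            rho = float("nan")
        else:
            rho = float(stats.spearmanr(curv[ok], scores[ok]).statistic)
        rows.append({"measure": spec.label(), "rho": rho, "n": int(ok.sum())})
    return pd.DataFrame(rows).set_index("measure")


def read_wedge_table(path: str | Path) -> WedgeParameters:
    """Load wedge angles from a ``dinucleotide<TAB>degrees`` TSV."""
    wedges = {}
    twist = 34.3
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            if line.startswith("#twist"):
                twist = float(line.split("\t")[1])
            continue
        dinuc, deg = line.split("\t")[:2]
        wedges[dinuc.upper()] = float(deg)
    return WedgeParameters(wedge_deg=wedges, twist_deg_per_step=twist)
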