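"""Reduced band configurations from attribution profiles.

P1 keeps the nine top attribution peaks (near-optimal retrieval with far
fewer channels); P2 keeps the three primary peaks under a wide separation
constraint, one per broad region of importance — the minimum viable
configuration.  Selections from several products/data types merge into the
combined minimum-viable (P2 union) and optimal (P1 union) configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .attribution import AttributionProfile

__all__ = ["BandSelection", "SelectionError", "find_peaks",
           "select_p1", "select_p2", "merge_configs",
           "selection_to_markdown", "save_selections_csv"]


class SelectionError(RuntimeError):
    """A profile does not yield enough peaks for the requested selection."""


@dataclass(frozen=True)
class BandSelection:
    """A named set of channel centers with provenance.

    name is one of {P1, P2, Full, merged}; source lists the (product,
    data_type) pairs the centers came from; counts (for merged selections)
    gives the number of source selections contributing each center.
    """

    name: str
    centers: tuple
    source: tuple = ()
    counts: tuple = ()

    def __post_init__(self):
        c = np.asarray(self.centers, dtype=float)
        if len(c) and np.any(np.diff(c) <= 0):
            raise ValueError("centers must be strictly increasing and unique")


def find_peaks(profile: AttributionProfile, min_sep_nm: float,
               smooth_window: int = 3):
    """Ranked local maxima of the (smoothed) attribution profile.

    The profile is smoothed with a moving average (window truncated at the
    edges), local maxima strictly greater than both immediate neighbors are
    collected (endpoints compete against their single neighbor), and a
    greedy pass by descending attribution discards candidates closer than
    min_sep_nm to an already accepted peak.  Returns (center, score) pairs
    ranked by descending attribution; ties break toward lower wavelength.
    """
    if min_sep_nm <= 0:
        raise ValueError("min_sep_nm must be > 0")
    centers = np.asarray(profile.channel_centers, dtype=float)
    fi = np.asarray(profile.fi, dtype=float)
    if len(centers) < 3:
        raise ValueError("profile must have at least 3 channels")
    w = max(1, int(smooth_window))
    kernel = np.ones(w)
    smooth = np.convolve(fi, kernel, mode="same") / np.convolve(
        np.ones_like(fi), kernel, mode="same")
    is_peak = np.zeros(len(fi), dtype=bool)
    is_peak[1:-1] = (smooth[1:-1] > smooth[:-2]) & (smooth[1:-1] > smooth[2:])
    is_peak[0] = smooth[0] > smooth[1]
    is_peak[-1] = smooth[-1] > smooth[-2]
    cand = np.where(is_peak)[0]
    order = np.lexsort((centers[cand], -smooth[cand]))
    accepted = []
    for i in cand[order]:
        if all(abs(centers[i] - c) >= min_sep_nm for c, _ in accepted):
            accepted.append((float(centers[i]), float(smooth[i])))
    return accepted


def _select(profile, n, min_sep_nm, name, smooth_window):
    peaks = find_peaks(profile, min_sep_nm, smooth_window=smooth_window)
    if len(peaks) < n:
        raise SelectionError(
            f"{name}: profile yields only {len(peaks)} peaks at "
            f"min_sep={min_sep_nm} nm; {n - len(peaks)} more needed")
    chosen = sorted(c for c, _ in peaks[:n])
    return BandSelection(name=name, centers=tuple(chosen),
                         source=((profile.product, profile.data_type),))


def select_p1(profile: AttributionProfile, n: int = 9,
              min_sep_nm: float = 9.0, smooth_window: int = 3) -> BandSelection:
    """The near-optimal configuration: the n (default 9) top attribution
    peaks, reported in ascending wavelength."""
    return _select(profile, n, min_sep_nm, "P1", smooth_window)


def select_p2(profile: AttributionProfile, n: int = 3,
              min_sep_nm: float = 30.0, smooth_window: int = 3) -> BandSelection:
    """The minimum viable configuration: the n (default 3) primary peaks
    under a wide separation constraint (one per broad importance region)."""
    return _select(profile, n, min_sep_nm, "P2", smooth_window)


def merge_configs(selections, tol_nm: float = 0.0) -> BandSelection:
    """Union of band selections with near-duplicate centers collapsed.

    Centers within tol_nm of each other collapse to one (the mean of the
    cluster); the per-center duplicate count is retained, mirroring the
    bold-marking of repeatedly selected bands in configuration tables.
    Commutative and idempotent.
    """
    selections = list(selections)
    if not selections:
        raise ValueError("merge_configs requires at least one selection")
    all_centers = sorted(c for sel in selections for c in sel.centers)
    clusters = [[all_centers[0]]]
    for c in all_centers[1:]:
        if c - clusters[-1][-1] <= tol_nm:
            clusters[-1].append(c)
        else:
            clusters.append([c])
    merged, counts = [], []
    for cl in clusters:
        merged.append(float(np.mean(cl)))
        counts.append(len(cl))
    source = tuple(dict.fromkeys(s for sel in selections for s in sel.source))
    return BandSelection(name="merged", centers=tuple(merged),
                         source=source, counts=tuple(counts))


def selection_to_markdown(selection: BandSelection) -> str:
    """Render a selection as a small Markdown table (bold = repeated bands)."""
    lines = [f"| band | center (nm) |", "|---|---|"]
    counts = selection.counts or (1,) * len(selection.centers)
    for i, (c, k) in enumerate(zip(selection.centers, counts), start=1):
        cell = f"**{c:g}**" if k > 1 else f"{c:g}"
        lines.append(f"| {i} | {cell} |")
    return "\n".join(lines)


def save_selections_csv(selections, path) -> pd.DataFrame:
    """Persist selections as tidy rows (name, center_nm, n_sources)."""
    rows = []
    for sel in selections:
        counts = sel.counts or (1,) * len(sel.centers)
        for c, k in zip(sel.centers, counts):
            rows.append({"name": sel.name, "center_nm": c, "n_sources": k})
    frame = pd.DataFrame(rows)
    frame.to_csv(Path(path), index=False)
    return frame
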