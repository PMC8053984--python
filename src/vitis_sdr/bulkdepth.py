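"""SDR delineation from bulk-pool windowed read depth.

A female bulk (all f/f) and a male bulk (all M/f) are mapped against the
two haplotype assemblies of a male accession.  Inside the SDR, unique
mapping splits the pools: the female bulk piles up at twofold depth on
the f assembly and contributes nothing to the M assembly, while the male
bulk maps at onefold depth on each.  The shared flanking sequence
collapses to a single representation, so both pools show twofold depth
there.  The longest window run matching the divergent pattern delineates
the SDR on each assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np

from .simulate import ASSEMBLIES, POOLS, WindowDepthTrack

#: fold-class thresholds on normalized depth (units of haploid coverage)
FOLD_2X_MIN = 1.5
FOLD_1X_MIN = 0.5

#: width of the majority-vote smoothing kernel (windows)
SMOOTH_KERNEL = 5


def normalize_track(track: WindowDepthTrack) -> WindowDepthTrack:
    """Scale raw depth so the flanking-region median sits at 2.0 units.

    Every window is divided by half the flank median; the flanks are
    shared diploid sequence, so this calibrates one unit to onefold
    (haploid) coverage.  Requires at least 20 flank windows.
    """
    flank = track.raw[track.flank_mask]
    if flank.size < 20:
        raise ValueError(f"need >= 20 flank windows for normalization, got {flank.size}")
    med = float(np.median(flank))
    if med == 0:
        raise ValueError("flank median depth is zero; cannot normalize")
    return replace(track, normalized=track.raw / (med / 2.0))


def classify_fold(normalized_depth) -> np.ndarray | str:
    """Fold class per window: '2x' >= 1.5, '1x' in [0.5, 1.5), else '0x'."""
    x = np.asarray(normalized_depth, dtype=float)
    if np.any(x < 0):
        raise ValueError("normalized depth must be non-negative")
    out = np.where(x >= FOLD_2X_MIN, "2x", np.where(x >= FOLD_1X_MIN, "1x", "0x"))
    return out.item() if out.ndim == 0 else out


def _majority_smooth(mask: np.ndarray, kernel: int = SMOOTH_KERNEL) -> np.ndarray:
    """Majority vote in a sliding window; tolerates isolated discordant calls."""
    kern = np.ones(kernel)
    votes = np.convolve(mask.astype(float), kern, mode="same")
    sizes = np.convolve(np.ones(mask.size), kern, mode="same")
    return votes * 2 > sizes


def _longest_run(mask: np.ndarray) -> tuple[int, int] | None:
    """(start_idx, stop_idx) of the longest True run, half-open; None if empty."""
    if not mask.any():
        return None
    padded = np.concatenate([[0], mask.astype(int), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    best = np.argmax(stops - starts)
    return int(starts[best]), int(stops[best])


@dataclass
class SdrDelineation:
    """Per-assembly SDR interval plus the flank diploidy diagnostic."""

    intervals: dict[str, tuple[int, int] | None]
    run_windows: dict[str, int]
    flank_2x_fraction: dict[tuple[str, str], float]


def delineate_sdr(
    tracks: Mapping[tuple[str, str], WindowDepthTrack],
    min_run_windows: int = 20,
) -> SdrDelineation:
    """Delineate the SDR from the four (pool x assembly) depth tracks.

    On the f assembly the SDR is the longest window run with the pattern
    (female-bulk 2x, male-bulk 1x); on the M assembly, (female-bulk 0x,
    male-bulk 1x).  Runs are smoothed by majority vote in a
    five-window kernel before extraction, and runs shorter than
    ``min_run_windows`` report an empty interval.  Boundaries are window
    edges.  The diagnostic records, per track, the fraction of flank
    windows classified 2x (both pools should be diploid in the flanks).
    """
    for key in [(p, a) for p in POOLS for a in ASSEMBLIES]:
        if key not in tracks:
            raise ValueError(f"missing track {key}")

    intervals: dict[str, tuple[int, int] | None] = {}
    run_windows: dict[str, int] = {}
    flank_frac: dict[tuple[str, str], float] = {}

    normalized = {}
    for key, track in tracks.items():
        t = track if track.normalized is not None else normalize_track(track)
        normalized[key] = t
        classes = classify_fold(t.normalized)
        flank_frac[key] = float((classes[t.flank_mask] == "2x").mean())

    for assembly in ASSEMBLIES:
        female = normalized[("female-bulk", assembly)]
        male = normalized[("male-bulk", assembly)]
        if female.window != male.window or female.starts.size != male.starts.size:
            raise ValueError("pool tracks on one assembly must share the window grid")
        target = "2x" if assembly == "f-hap" else "0x"
        qual = (classify_fold(female.normalized) == target) & (
            classify_fold(male.normalized) == "1x"
        )
        qual = _majority_smooth(qual)
        run = _longest_run(qual)
        if run is None or run[1] - run[0] < min_run_windows:
            intervals[assembly] = None
            run_windows[assembly] = 0 if run is None else run[1] - run[0]
            continue
        i0, i1 = run
        intervals[assembly] = (int(female.starts[i0]), int(female.ends[i1 - 1]))
        run_windows[assembly] = i1 - i0

    return SdrDelineation(
        intervals=intervals, run_windows=run_windows, flank_2x_fraction=flank_frac
    )
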