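"""Per-base metaprofiles of dyad density around aligned site anchors.

The metaprofile is the workhorse of barrier-model phasing analysis: fragment
midpoints (dyad proxies) are counted at every base of a window centered on
each binding-site anchor, summed over sites, normalized by the number of
sites and the sequencing depth, rescaled to a common window mean so that
conditions with different depths are directly comparable, and finally
smoothed with a sliding window for peak calling and display.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RawProfile",
    "DyadProfile",
    "aggregate",
    "normalize",
    "smooth",
    "occupancy_in_center",
]


@dataclass(frozen=True)
class RawProfile:
    """Unnormalized per-base dyad counts over a symmetric window.

    ``counts[i]`` is the number of (dyad, anchor) pairs at signed offset
    ``i - half_window``; the window spans ``2 * half_window + 1`` bases
    inclusive of both endpoints.
    """

    half_window: int
    counts: np.ndarray
    n_sites: int
    total_fragments: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (2 * self.half_window + 1,):
            raise ValueError(
                f"counts length {counts.shape} does not match window "
                f"{2 * self.half_window + 1}"
            )
        if (counts < 0).any():
            raise ValueError("negative counts")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.half_window, self.half_window + 1)


@dataclass(frozen=True)
class DyadProfile:
    """Normalized (optionally smoothed) dyad-density metaprofile."""

    half_window: int
    values: np.ndarray
    n_sites: int
    total_fragments: int
    smoothing_bp: int = 0
    rescaled_mean: float = 1.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (2 * self.half_window + 1,):
            raise ValueError("values length does not match window")

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.half_window, self.half_window + 1)

    def value_at(self, offset: int) -> float:
        return float(self.values[offset + self.half_window])


def aggregate(
    dyads: Iterable[tuple[str, int]],
    anchors: Sequence[tuple[str, int, int]],
    half_window: int = 1000,
) -> RawProfile:
    """Count dyads at each signed offset from every anchor.

    ``anchors`` are ``(chrom, position, orientation_sign)`` triples as
    produced by :func:`nucphase.sites.site_anchor`. A dyad lying inside
    several overlapping windows contributes once per window.
    ``total_fragments`` records the full experiment size (all dyads passed
    in, inside the windows or not), which is the depth-normalization
    constant used downstream.
    """
    if not anchors:
        raise ValueError("anchors must be non-empty")
    by_chrom: dict[str, list[int]] = {}
    total = 0
    for chrom, pos in dyads:
        by_chrom.setdefault(chrom, []).append(pos)
        total += 1
    sorted_dyads = {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in by_chrom.items()}

    counts = np.zeros(2 * half_window + 1, dtype=np.int64)
    for chrom, pos, sign in anchors:
        d = sorted_dyads.get(chrom)
        if d is None or d.size == 0:
            continue
        lo = np.searchsorted(d, pos - half_window, side="left")
        hi = np.searchsorted(d, pos + half_window, side="right")
        if hi > lo:
            offs = (d[lo:hi] - pos) * sign
            np.add.at(counts, offs + half_window, 1)
    return RawProfile(
        half_window=half_window,
        counts=counts,
        n_sites=len(anchors),
        total_fragments=total,
    )


def normalize(raw: RawProfile, rescaled_mean: float = 1.0) -> DyadProfile:
    """Normalize a raw profile to a common window mean.

    Two steps, both recorded in the output: the counts are divided by
    ``n_sites * total_fragments`` (per-site, per-read density), then scaled
    by one constant so the window mean equals ``rescaled_mean``.
    """
    if raw.counts.sum() == 0:
        raise ValueError("no signal in window: all counts are zero")
    v = raw.counts / (raw.n_sites * max(raw.total_fragments, 1))
    v = v * (rescaled_mean / v.mean())
    return DyadProfile(
        half_window=raw.half_window,
        values=v,
        n_sites=raw.n_sites,
        total_fragments=raw.total_fragments,
        smoothing_bp=0,
        rescaled_mean=rescaled_mean,
    )


def smooth(profile: DyadProfile, window_bp: int = 50) -> DyadProfile:
    """Centered moving average over ``window_bp`` bases.

    An even window is widened by one base so the filter has a well-defined
    center (50 -> 51). At the window edges the averaging window shrinks
    symmetrically to fit, and the result is re-rescaled so the window mean
    stays exactly at ``rescaled_mean``.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    if window_bp % 2 == 0:
        window_bp += 1
    n = profile.values.size
    if window_bp > n:
        raise ValueError(f"smoothing window {window_bp} exceeds profile length {n}")
    half = window_bp // 2
    v = profile.values
    csum = np.concatenate(([0.0], np.cumsum(v)))
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo, hi = idx - h, idx + h
    out = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    out *= profile.rescaled_mean / out.mean()
    return replace(profile, values=out, smoothing_bp=window_bp)


def occupancy_in_center(profile: DyadProfile, center_halfwidth: int = 73) -> float:
    """Mean profile value over the central band ``|offset| <= center_halfwidth``.

    With the default half-width of 73 bp the band covers one nucleosome core
    footprint centered on the binding site, so the statistic tracks
    nucleosome occupancy of the site sequence itself.
    """
    if center_halfwidth > profile.half_window:
        raise ValueError("center_halfwidth exceeds the profile window")
    hw = profile.half_window
    band = profile.values[hw - center_halfwidth : hw + center_halfwidth + 1]
    return float(band.mean())
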