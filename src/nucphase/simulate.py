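"""Synthetic phased-chromatin generator.

Implements a barrier model of nucleosome phasing: a bound transcription
factor acts as a boundary, the +1 and -1 nucleosome dyads sit at
``+/- plus_one_distance / 2`` from the site center, and further nucleosomes
follow outward on a lattice with spacing ``nrl``. Positional noise grows
linearly with array index, reproducing the decay of phasing with distance
from the barrier. Unbound sites instead carry a fuzzy nucleosome centered on
the site, modelling the high intrinsic nucleosome affinity of vacant CTCF
sequences. MNase digestion extent is modelled by geometric single-sided
linker overhangs added to the 147 bp protected core, so the analytic mean
fragment length is ``core_bp + 2 * overhang_mean`` (147 bp for a full
digest, 169 bp for a light digest with 11 bp mean overhangs).

The generators also emit synthetic ChIP fragments (Gaussian peaks at sites
over a uniform background) and paired differential-expression tables with a
correlated shared-effect gene subset, so the downstream occupancy and
co-regulation analyses are testable without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io import FragmentRecord, GeneRecord, SiteRecord

__all__ = [
    "ArrayModel",
    "DigestionModel",
    "ScenarioSpec",
    "SCENARIO_NAMES",
    "SITE_WINDOW_HALFWIDTH",
    "simulate_sites",
    "simulate_fragments",
    "scenario_presets",
    "simulate_chip_fragments",
    "simulate_de_tables",
]

#: Half-width (bp) of the per-site window used for background dyad placement;
#: matches the default metaprofile window.
SITE_WINDOW_HALFWIDTH = 1000

#: Placement s.d. (bp) of the site-centered nucleosome on unbound sites.
#: Vacant sites carry a well-populated but imprecisely positioned nucleosome.
UNBOUND_FUZZ_SD = 15.0

SCENARIO_NAMES = ("control", "snf2h_depleted", "snf2l_depleted", "ctcf_depleted")


@dataclass(frozen=True)
class ArrayModel:
    """Barrier-array geometry and noise for one condition.

    nrl
        Nucleosome repeat length: center-to-center spacing within each flank
        (bp).
    plus_one_distance
        Dyad-to-dyad distance between the +1 and -1 nucleosomes across the
        site (bp); at least one core footprint.
    n_per_side
        Nucleosomes per flank.
    jitter_sd0 / jitter_growth
        Gaussian placement s.d. of the +1/-1 dyad, and the additional s.d.
        per array index outward, so phasing decays with distance from the
        barrier.
    background_rate
        Unpositioned background dyads per bp per site window.
    bound_fraction
        Fraction of sites occupied by the factor; unbound sites get a
        site-centered nucleosome instead of an array.
    """

    nrl: float = 176.0
    plus_one_distance: float = 280.0
    n_per_side: int = 10
    jitter_sd0: float = 2.0
    jitter_growth: float = 2.0
    background_rate: float = 0.002
    bound_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.nrl <= 0:
            raise ValueError("nrl must be > 0")
        if self.plus_one_distance < 147:
            raise ValueError("plus_one_distance must be >= 147 (one core footprint)")
        if not 0.0 <= self.bound_fraction <= 1.0:
            raise ValueError("bound_fraction must be in [0, 1]")
        for name in ("jitter_sd0", "jitter_growth", "background_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class DigestionModel:
    """Fragment-length model: protected core plus geometric linker overhangs."""

    core_bp: int = 147
    overhang_mean: float = 0.0
    dyads_per_site: float = 30.0

    def __post_init__(self) -> None:
        if self.core_bp < 1:
            raise ValueError("core_bp must be >= 1")
        if self.overhang_mean < 0:
            raise ValueError("overhang_mean must be >= 0")

    @property
    def mean_fragment_length(self) -> float:
        """Analytic mean: core plus two independent one-sided overhangs."""
        return self.core_bp + 2.0 * self.overhang_mean


@dataclass(frozen=True)
class ScenarioSpec:
    """A named simulation condition: array geometry, digestion, seed."""

    name: str
    array: ArrayModel
    digestion: DigestionModel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.name!r}; use one of {SCENARIO_NAMES}")


def scenario_presets() -> Mapping[str, ScenarioSpec]:
    """The four named depletion scenarios.

    Control and each depleted preset share every parameter except the ones
    the named scenario perturbs:

    * ``control`` -- 176 bp repeat length adjacent to the bound factor.
    * ``snf2h_depleted`` -- repeat length relaxes to 183 bp, the +1/-1
      distance widens by 25 bp, and arrays decay faster (larger jitter
      growth): loss of the dominant spacing activity.
    * ``snf2l_depleted`` -- repeat length tightens to 173 bp and the +1/-1
      distance shrinks by 10 bp: nucleosomes drift toward the bound factor.
    * ``ctcf_depleted`` -- the barrier itself is lost at most sites
      (``bound_fraction`` drops), so formerly bound sites revert to
      center-occupied, unphased chromatin.
    """
    control_array = ArrayModel()
    digestion = DigestionModel()
    return {
        "control": ScenarioSpec("control", control_array, digestion),
        "snf2h_depleted": ScenarioSpec(
            "snf2h_depleted",
            replace(
                control_array,
                nrl=183.0,
                plus_one_distance=control_array.plus_one_distance + 25.0,
                jitter_growth=5.0,
            ),
            digestion,
        ),
        "snf2l_depleted": ScenarioSpec(
            "snf2l_depleted",
            replace(
                control_array,
                nrl=173.0,
                plus_one_distance=control_array.plus_one_distance - 10.0,
            ),
            digestion,
        ),
        "ctcf_depleted": ScenarioSpec(
            "ctcf_depleted",
            replace(control_array, bound_fraction=0.3),
            digestion,
        ),
    }


def simulate_sites(
    n_sites: int,
    chrom_length: int,
    min_gap: int,
    seed: int,
    chrom: str = "chrS",
    site_width: int = 19,
) -> list[SiteRecord]:
    """Place non-overlapping sites uniformly with pairwise center gap >= min_gap.

    An edge margin of one site window half-width keeps the analysis windows
    of the outermost sites on the chromosome. Raises ``ValueError`` when the
    packing is infeasible.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    margin = SITE_WINDOW_HALFWIDTH
    span = chrom_length - 2 * margin - (n_sites - 1) * min_gap
    if span <= 0:
        raise ValueError(
            f"cannot place {n_sites} sites with min_gap {min_gap} on a "
            f"{chrom_length} bp chromosome"
        )
    rng = np.random.default_rng(seed)
    slack = np.sort(rng.uniform(0.0, span, size=n_sites))
    centers = (margin + slack + np.arange(n_sites) * min_gap).astype(np.int64)
    half = site_width // 2
    return [
        SiteRecord(chrom, int(c - half), int(c - half + site_width), name=f"site{i}")
        for i, c in enumerate(centers)
    ]


def _geometric_overhangs(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Geometric overhang lengths on {0, 1, 2, ...} with the given mean."""
    if mean == 0 or size == 0:
        return np.zeros(size, dtype=np.int64)
    p = 1.0 / (1.0 + mean)
    return rng.geometric(p, size=size).astype(np.int64) - 1


def simulate_fragments(
    sites: Sequence[SiteRecord], spec: ScenarioSpec
) -> tuple[list[FragmentRecord], int]:
    """Sample nucleosomal fragments for a cohort of sites under one scenario.

    Returns ``(fragments, n_clipped)`` where ``n_clipped`` counts fragments
    whose start was clipped at coordinate 0. For each bound site
    (probability ``bound_fraction``) dyads are placed on the two-sided
    lattice ``+/-(plus_one_distance / 2 + k * nrl)``, ``k = 0 ..
    n_per_side - 1``, each lattice point sampled
    ``Poisson(dyads_per_site / (2 * n_per_side))`` times with Gaussian
    jitter of s.d. ``jitter_sd0 + k * jitter_growth``. Unbound sites get
    ``Poisson(dyads_per_site)`` dyads at the site center (s.d.
    ``UNBOUND_FUZZ_SD``). Background dyads arrive as
    ``Poisson(background_rate)`` per bp over each site window. Every dyad
    becomes a fragment ``[dyad - core//2 - L_left, dyad + core - core//2 +
    L_right)`` with independent geometric overhangs of mean
    ``overhang_mean``.
    """
    if not sites:
        raise ValueError("sites must be non-empty")
    arr, dig = spec.array, spec.digestion
    rng = np.random.default_rng(spec.seed)
    centers = np.array([s.center for s in sites], dtype=np.float64)
    chrom = sites[0].chrom
    if any(s.chrom != chrom for s in sites):
        raise ValueError("simulate_fragments expects sites on a single chromosome")

    bound = rng.random(centers.size) < arr.bound_fraction
    bound_centers = centers[bound]
    dyads: list[np.ndarray] = []

    lam = dig.dyads_per_site / (2 * arr.n_per_side)
    for k in range(arr.n_per_side):
        lattice_offset = arr.plus_one_distance / 2.0 + k * arr.nrl
        sd = arr.jitter_sd0 + k * arr.jitter_growth
        for sign in (1.0, -1.0):
            counts = rng.poisson(lam, size=bound_centers.size)
            pos = np.repeat(bound_centers + sign * lattice_offset, counts)
            if sd > 0 and pos.size:
                pos = pos + rng.normal(0.0, sd, size=pos.size)
            dyads.append(pos)

    unbound_centers = centers[~bound]
    counts = rng.poisson(dig.dyads_per_site, size=unbound_centers.size)
    pos = np.repeat(unbound_centers, counts)
    if pos.size:
        pos = pos + rng.normal(0.0, UNBOUND_FUZZ_SD, size=pos.size)
    dyads.append(pos)

    window_bp = 2 * SITE_WINDOW_HALFWIDTH
    n_bg = rng.poisson(arr.background_rate * window_bp, size=centers.size)
    bg = np.repeat(centers, n_bg)
    if bg.size:
        bg = bg + rng.uniform(-SITE_WINDOW_HALFWIDTH, SITE_WINDOW_HALFWIDTH, size=bg.size)
    dyads.append(bg)

    dyad = np.rint(np.concatenate(dyads)).astype(np.int64)
    left = _geometric_overhangs(rng, dig.overhang_mean, dyad.size)
    right = _geometric_overhangs(rng, dig.overhang_mean, dyad.size)
    start = dyad - dig.core_bp // 2 - left
    end = dyad + (dig.core_bp - dig.core_bp // 2) + right
    n_clipped = int((start < 0).sum())
    start = np.maximum(start, 0)
    frags = [
        FragmentRecord(chrom, int(s), int(e)) for s, e in zip(start, end) if e > s
    ]
    return frags, n_clipped


def simulate_chip_fragments(
    sites: Sequence[SiteRecord],
    enrichment: float,
    peak_sd: float,
    n_fragments: int,
    frag_len_mean: int,
    seed: int,
    chrom_length: int | None = None,
) -> list[FragmentRecord]:
    """Sample ChIP fragments: per-site Gaussian peaks over a uniform background.

    ``enrichment`` is the midpoint density at a site center relative to the
    background density (so ``enrichment=1`` is a flat track). The signal
    weight per site is chosen so the peak of the Gaussian mixture component
    stands at exactly ``(enrichment - 1)`` times the background level.
    """
    if enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    if not sites:
        raise ValueError("sites must be non-empty")
    chrom = sites[0].chrom
    centers = np.array([s.center for s in sites], dtype=np.float64)
    if chrom_length is None:
        chrom_length = int(centers.max()) + SITE_WINDOW_HALFWIDTH
    rng = np.random.default_rng(seed)

    # per-site signal mass s relative to background mass b (both in fragment
    # counts): peak height s / (peak_sd * sqrt(2 pi)) = (enrichment - 1) * b / G
    s_over_b = (enrichment - 1.0) * peak_sd * math.sqrt(2.0 * math.pi) / chrom_length
    p_background = 1.0 / (1.0 + centers.size * s_over_b)
    is_bg = rng.random(n_fragments) < p_background
    mids = np.empty(n_fragments, dtype=np.float64)
    mids[is_bg] = rng.uniform(0.0, chrom_length, size=int(is_bg.sum()))
    n_sig = int((~is_bg).sum())
    if n_sig:
        which = rng.integers(0, centers.size, size=n_sig)
        mids[~is_bg] = centers[which] + rng.normal(0.0, peak_sd, size=n_sig)
    mid = np.rint(mids).astype(np.int64)
    start = np.maximum(mid - frag_len_mean // 2, 0)
    end = start + frag_len_mean
    return [FragmentRecord(chrom, int(s), int(e)) for s, e in zip(start, end)]


def simulate_de_tables(
    n_genes: int,
    n_shared: int,
    n_private_a: int,
    n_private_b: int,
    effect_log2fc_sd: float = 1.5,
    rho_target: float = 0.8,
    seed: int = 0,
) -> tuple[list[GeneRecord], list[GeneRecord]]:
    """Paired differential-expression tables over a shared gene universe.

    ``n_shared`` genes respond in both tables with bivariate-normal log2
    fold changes tuned so their Spearman correlation approaches
    ``rho_target`` (the Pearson parameter is ``2 sin(pi rho / 6)``, the
    inverse of the normal rank-correlation identity). Each table
    additionally has private responders sampled independently of the other
    table's, so with ``n_shared=0`` the two significant sets are independent
    draws and the overlap test is null-calibrated. The remaining genes are
    null (fold change near 1, uniform p). q-values come from
    Benjamini-Hochberg within each table.
    """
    if n_shared + n_private_a > n_genes or n_shared + n_private_b > n_genes:
        raise ValueError("affected gene counts exceed the universe size")
    if not -1.0 <= rho_target <= 1.0:
        raise ValueError("rho_target must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    ids = np.array([f"gene{i:05d}" for i in range(n_genes)])

    shared_idx = rng.choice(n_genes, size=n_shared, replace=False)
    rest = np.setdiff1d(np.arange(n_genes), shared_idx)
    private_a = rng.choice(rest, size=n_private_a, replace=False)
    # sampled independently of private_a (may overlap by chance): keeps the
    # two tables' responder sets independent when n_shared = 0
    private_b = rng.choice(rest, size=n_private_b, replace=False)

    pearson = 2.0 * math.sin(math.pi * rho_target / 6.0)
    cov = (effect_log2fc_sd**2) * np.array([[1.0, pearson], [pearson, 1.0]])
    shared_fc = rng.multivariate_normal([0.0, 0.0], cov, size=n_shared)

    def build(affected_private: np.ndarray, shared_col: int) -> list[GeneRecord]:
        log2fc = rng.normal(0.0, 0.05, size=n_genes)
        p = rng.uniform(0.0, 1.0, size=n_genes)
        if n_shared:
            log2fc[shared_idx] = shared_fc[:, shared_col]
        log2fc[affected_private] = rng.normal(
            0.0, effect_log2fc_sd, size=affected_private.size
        )
        affected = np.concatenate([shared_idx, affected_private])
        p[affected] = rng.uniform(0.0, 1e-3, size=affected.size)
        q = multipletests(p, method="fdr_bh")[1]
        return [
            GeneRecord(ids[i], float(2.0 ** log2fc[i]), float(p[i]), float(q[i]))
            for i in range(n_genes)
        ]

    return build(private_a, 0), build(private_b, 1)
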