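import dataclasses

import numpy as np
import pytest

from nucphase.fragments import fragment_midpoints
from nucphase.simulate import (
    ArrayModel,
    DigestionModel,
    ScenarioSpec,
    scenario_presets,
    simulate_chip_fragments,
    simulate_de_tables,
    simulate_fragments,
    simulate_sites,
)


def noiseless_spec(seed=0, **digestion_kw):
    return ScenarioSpec(
        "control",
        ArrayModel(jitter_sd0=0, jitter_growth=0, background_rate=0, bound_fraction=1.0),
        DigestionModel(**digestion_kw),
        seed=seed,
    )


class TestSimulateSites:
    def test_min_center_distance_respected(self):
        sites = simulate_sites(2, 10_000, 3000, seed=4)
        assert len(sites) == 2
        assert abs(sites[1].center - sites[0].center) >= 3000

    def test_determinism(self):
        assert simulate_sites(20, 300_000, 3000, seed=9) == simulate_sites(
            20, 300_000, 3000, seed=9
        )

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError):
            simulate_sites(10, 5_000, 2000, seed=0)

    def test_sites_are_19bp_nonoverlapping(self):
        sites = simulate_sites(50, 1_000_000, 3000, seed=2)
        assert all(s.end - s.start == 19 for s in sites)
        centers = [s.center for s in sites]
        assert min(np.diff(centers)) >= 3000


class TestSimulateFragments:
    def test_noiseless_midpoints_on_lattice(self):
        sites = simulate_sites(10, 200_000, 4000, seed=1)
        frags, n_clipped = simulate_fragments(sites, noiseless_spec())
        assert n_clipped == 0
        lattice = {
            int(c + s * (280 / 2 + k * 176))
            for c in (site.center for site in sites)
            for s in (-1, 1)
            for k in range(10)
        }
        mids = {pos for _, pos in fragment_midpoints(frags)}
        assert mids <= lattice

    def test_zero_overhang_gives_core_length(self):
        sites = simulate_sites(10, 200_000, 4000, seed=1)
        frags, _ = simulate_fragments(sites, noiseless_spec(overhang_mean=0.0))
        assert {f.length for f in frags} == {147}

    def test_mean_length_matches_analytic_within_3se(self):
        sites = simulate_sites(700, 6_000_000, 3000, seed=6)
        spec = noiseless_spec(seed=6, overhang_mean=11.0, dyads_per_site=150.0)
        frags, _ = simulate_fragments(sites, spec)
        lengths = np.array([f.length for f in frags])
        assert lengths.size >= 100_000
        se = lengths.std() / np.sqrt(lengths.size)
        assert abs(lengths.mean() - spec.digestion.mean_fragment_length) < 3 * se

    def test_determinism_byte_identical(self):
        sites = simulate_sites(20, 300_000, 4000, seed=3)
        spec = scenario_presets()["control"]
        spec = dataclasses.replace(spec, seed=77)
        a, ca = simulate_fragments(sites, spec)
        b, cb = simulate_fragments(sites, spec)
        assert a == b and ca == cb

    def test_empty_sites_rejected(self):
        with pytest.raises(ValueError):
            simulate_fragments([], noiseless_spec())

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError):
            ArrayModel(nrl=-1)
        with pytest.raises(ValueError):
            ArrayModel(bound_fraction=1.5)
        with pytest.raises(ValueError):
            DigestionModel(overhang_mean=-2)
        with pytest.raises(ValueError):
            ScenarioSpec("weird", ArrayModel(), DigestionModel())


class TestScenarioPresets:
    def test_control_spacing_value(self):
        assert scenario_presets()["control"].array.nrl == 176

    def test_depletion_repeat_lengths(self):
        presets = scenario_presets()
        assert presets["snf2h_depleted"].array.nrl == 183
        assert presets["snf2l_depleted"].array.nrl == 173

    def test_plus_one_distance_shifts(self):
        presets = scenario_presets()
        base = presets["control"].array.plus_one_distance
        assert presets["snf2h_depleted"].array.plus_one_distance - base == 25
        assert presets["snf2l_depleted"].array.plus_one_distance - base == -10

    def test_ctcf_depletion_lowers_bound_fraction_only(self):
        presets = scenario_presets()
        c, d = presets["control"].array, presets["ctcf_depleted"].array
        assert d.bound_fraction < c.bound_fraction
        assert dataclasses.replace(d, bound_fraction=c.bound_fraction) == c

    def test_presets_share_all_but_perturbed_parameters(self):
        presets = scenario_presets()
        c = presets["control"].array
        h = presets["snf2h_depleted"].array
        same = dataclasses.replace(
            h, nrl=c.nrl, plus_one_distance=c.plus_one_distance, jitter_growth=c.jitter_growth
        )
        assert same == c
        assert presets["control"].digestion == presets["snf2h_depleted"].digestion


class TestSimulateChip:
    def test_no_enrichment_is_flat(self):
        sites = simulate_sites(50, 2_000_000, 3000, seed=5)
        frags = simulate_chip_fragments(
            sites, enrichment=1.0, peak_sd=100, n_fragments=50_000,
            frag_len_mean=200, seed=5, chrom_length=2_000_000,
        )
        mids = np.array([f.midpoint for f in frags])
        hist, _ = np.histogram(mids, bins=20, range=(0, 2_000_000))
        assert hist.min() > 0.8 * hist.mean() and hist.max() < 1.2 * hist.mean()

    def test_enrichment_concentrates_at_sites(self):
        sites = simulate_sites(50, 2_000_000, 3000, seed=5)
        frags = simulate_chip_fragments(
            sites, enrichment=10.0, peak_sd=100, n_fragments=50_000,
            frag_len_mean=200, seed=5, chrom_length=2_000_000,
        )
        mids = np.array([f.midpoint for f in frags])
        centers = np.array([s.center for s in sites])
        near = np.zeros(mids.size, dtype=bool)
        for c in centers:
            near |= np.abs(mids - c) < 300
        covered = 600 * centers.size / 2_000_000
        assert near.mean() > 3 * covered  # far above the uniform expectation

    def test_determinism(self):
        sites = simulate_sites(5, 100_000, 3000, seed=1)
        kw = dict(enrichment=5.0, peak_sd=80, n_fragments=500, frag_len_mean=150, seed=42)
        assert simulate_chip_fragments(sites, **kw) == simulate_chip_fragments(sites, **kw)

    def test_enrichment_below_one_rejected(self):
        sites = simulate_sites(5, 100_000, 3000, seed=1)
        with pytest.raises(ValueError):
            simulate_chip_fragments(sites, 0.5, 100, 100, 150, 0)


class TestSimulateDeTables:
    def test_perfect_correlation_degenerate_limit(self):
        from nucphase.coregulation import coregulation_analysis

        a, b = simulate_de_tables(500, 120, 0, 0, rho_target=1.0, seed=8)
        res = coregulation_analysis(a, b)
        assert res.spearman_rho == pytest.approx(1.0, abs=1e-9)

    def test_bh_q_monotone_in_p_rank(self):
        a, _ = simulate_de_tables(400, 50, 40, 40, seed=3)
        ordered = sorted(a, key=lambda g: g.p_value)
        q = [g.q_value for g in ordered]
        assert all(q1 <= q2 + 1e-12 for q1, q2 in zip(q, q[1:]))

    def test_study_scale_smoke(self):
        # mirrors the scale of the study: 3294 measured genes, ~1000 flagged
        from nucphase.coregulation import filter_significant

        a, b = simulate_de_tables(3294, 700, 600, 600, seed=1)
        na, nb = len(filter_significant(a)), len(filter_significant(b))
        assert 600 < na < 1400 and 600 < nb < 1400

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ValueError):
            simulate_de_tables(100, 80, 30, 0)

    def test_universe_and_determinism(self):
        a1, b1 = simulate_de_tables(200, 20, 10, 10, seed=5)
        a2, b2 = simulate_de_tables(200, 20, 10, 10, seed=5)
        assert a1 == a2 and b1 == b2
        assert {g.gene_id for g in a1} == {g.gene_id for g in b1}
        assert len(a1) == 200
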