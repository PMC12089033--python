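import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import microzone as mz
from microzone._rng import substream
from microzone.granular import FileCode
from microzone.molecular import (
    DegenerateInputError,
    MolecularError,
    StellateSampleLaw,
    build_pc_afferent_networks,
    integrate_pc,
    simulate_stellate_layer,
)

# the probability table the contact law reproduces (x = 0..12, 4 dp)
CONTACT_TABLE = [
    0.0066, 0.0331, 0.0836, 0.1403, 0.1762, 0.1765, 0.1470,
    0.1047, 0.0651, 0.0359, 0.0178, 0.0080, 0.0033,
]


def constant_files(geom, value=100.0, n_pool=500):
    return [
        FileCode(j, np.full(n_pool, value), geom.n_ranks * geom.granule_per_field)
        for j in range(geom.n_sectors)
    ]


class TestStellateSampleLaw:
    def test_printed_probability_table(self):
        law = StellateSampleLaw()
        for x, expected in enumerate(CONTACT_TABLE):
            assert round(mz.stellate_sample_size_pmf(x, law), 4) == expected

    def test_pmf_normalises_and_exact_mean_is_five(self, default_geom):
        law = StellateSampleLaw.from_geometry(default_geom)
        assert law.p_contact == pytest.approx(1 / 84)
        assert np.sum(law.pmf(np.arange(law.n_active + 1))) == pytest.approx(1.0)
        assert law.mean == pytest.approx(5.0)

    def test_domain_error(self):
        law = StellateSampleLaw()
        with pytest.raises(MolecularError):
            law.pmf(-1)
        with pytest.raises(MolecularError):
            law.pmf(421)

    def test_truncated_sampling_never_zero(self, rng):
        x = StellateSampleLaw(truncate_zero=True).sample(rng, 20_000)
        assert x.min() >= 1
        assert x.mean() == pytest.approx(5.0 / (1 - 0.0066), rel=0.05)

    @given(n=st.integers(50, 600), p=st.floats(0.001, 0.05))
    def test_pmf_normalisation_property(self, n, p):
        law = StellateSampleLaw(n_active=n, p_contact=p)
        total = np.sum(law.pmf(np.arange(n + 1)))
        assert total == pytest.approx(1.0, abs=1e-9)


class TestStellateLayer:
    def test_constant_pool_propagates(self, default_geom, rng):
        files = constant_files(default_geom, 42.0)
        res = simulate_stellate_layer(files, StellateSampleLaw(), default_geom, rng)
        assert np.all(res.outputs == 42.0)

    def test_unit_count_and_file_confinement(self, default_geom, rng):
        # give each file a distinctive rate so cross-file sampling is visible
        files = [
            FileCode(j, np.full(300, float(j)), 41 * 9000)
            for j in range(default_geom.n_sectors)
        ]
        res = simulate_stellate_layer(files, StellateSampleLaw(), default_geom, rng)
        assert res.n_units == 8000
        np.testing.assert_array_equal(res.outputs, res.sector.astype(float))

    def test_empty_pool_names_sector(self, default_geom, rng):
        files = constant_files(default_geom)
        files[37] = FileCode(37, np.empty(0), 41 * 9000)
        with pytest.raises(DegenerateInputError, match="37"):
            simulate_stellate_layer(files, StellateSampleLaw(), default_geom, rng)

    def test_output_sd_matches_sampling_law_oracle(self, default_geom, rng):
        """SD of stellate outputs ~ pool SD x sqrt(E[1/x]) under the contact
        law (Monte-Carlo oracle with pmf-weighted sample sizes)."""
        law = StellateSampleLaw()
        pool = rng.normal(125, 10, 2000)
        files = [
            FileCode(j, pool, 41 * 9000) for j in range(default_geom.n_sectors)
        ]
        res = simulate_stellate_layer(files, law, default_geom, rng)

        oracle_rng = np.random.default_rng(11)
        x = law.sample(oracle_rng, 100_000)
        expected_sd = pool.std() * np.sqrt(np.mean(1.0 / x))
        assert res.outputs.std() == pytest.approx(expected_sd, rel=0.10)


class TestPcNetworks:
    def test_flank_sizes(self, default_geom):
        nets = build_pc_afferent_networks(default_geom, substream(3, "networks"))
        assert len(nets) == default_geom.pcs_total
        for net in nets:
            lo, hi = (16, 32) if 0 < net.sector < 99 else (16, 24)
            for flank in net.flanks:
                assert lo <= flank.size <= hi
                assert flank.size == np.unique(flank).size

    def test_same_sector_flanks_disjoint(self, default_geom):
        nets = build_pc_afferent_networks(default_geom, substream(3, "networks"))
        per = default_geom.stellate_per_sector
        for net in nets[:40]:
            own = [f[f // per == net.sector] for f in net.flanks]
            assert np.intersect1d(own[0], own[1]).size == 0
            assert own[0].size == own[1].size == default_geom.stellate_per_flank

    def test_neighbour_afferents_exclude_outer_layers(self, default_geom):
        nets = build_pc_afferent_networks(default_geom, substream(5, "networks"))
        per = default_geom.stellate_per_sector
        flank_n = default_geom.stellate_per_flank
        for net in nets:
            for flank in net.flanks:
                neighbours = flank[flank // per != net.sector]
                layers = (neighbours % per) // flank_n
                assert np.all(layers >= 2)  # inner depth levels only


class TestPurkinjeIntegration:
    def test_constant_network_propagates(self, default_geom):
        files = constant_files(default_geom, 7.0)
        st_res = simulate_stellate_layer(
            files, StellateSampleLaw(), default_geom, substream(1, "st")
        )
        nets = build_pc_afferent_networks(default_geom, substream(1, "net"))
        pcs = integrate_pc(st_res, nets, default_geom, substream(1, "pc"))
        np.testing.assert_allclose(pcs.compartments, 7.0)
        np.testing.assert_allclose(pcs.soma, 7.0)

    def test_output_counts_and_soma_is_compartment_mean(self, mid_run):
        pcs = mid_run.pcs
        assert pcs.n_cells == mid_run.geom.pcs_total
        np.testing.assert_allclose(pcs.soma, pcs.compartments.mean(axis=1))
        np.testing.assert_allclose(
            pcs.compartments, pcs.compartments_by_flank.mean(axis=1)
        )

    def test_narrowing_cascade_and_mean_conservation(self, mid_run):
        """The defining signature of the cascade: each sampling step narrows
        the distribution while conserving its mean."""
        pf = np.concatenate([fc.pf_rates for fc in mid_run.files])
        sds = [
            pf.std(),
            mid_run.stellate.outputs.std(),
            mid_run.pcs.compartments.std(),
            mid_run.pcs.soma.std(),
            mid_run.nuclear.outputs.std(),
        ]
        assert all(a > b for a, b in zip(sds, sds[1:]))
        cons = mz.mean_conservation(mid_run)
        assert cons["within_3se"].all()

    def test_shape_invariance_of_narrowing(self, mid_geom):
        """Uniform, normal (SD 40) and discontinuous (50-300 Hz) inputs give
        the same narrowing profile."""
        from microzone.mossy import RankInputSpec
        from microzone.pipeline import SimulationConfig

        profiles = {}
        for name, spec in {
            "uniform": RankInputSpec.uniform(0, 250),
            "normal": RankInputSpec.normal(125, 40),
            "discontinuous": RankInputSpec.discontinuous([(50, 110), (180, 300)]),
        }.items():
            cfg = SimulationConfig(geometry=mid_geom, input=spec)
            run = mz.simulate(cfg, seed=2)
            pf = np.concatenate([fc.pf_rates for fc in run.files])
            sds = np.array(
                [
                    pf.std(),
                    run.stellate.outputs.std(),
                    run.pcs.compartments.std(),
                    run.pcs.soma.std(),
                ]
            )
            profiles[name] = sds / sds[0]  # narrowing relative to pf spread
        for name, prof in profiles.items():
            assert np.all(np.diff(prof) < 0), name
        ratios = np.array(list(profiles.values()))
        # same profile across shapes: relative SDs agree within a factor ~2
        assert np.all(ratios.max(axis=0) / ratios.min(axis=0) < 2.0)

    def test_small_flank_rejected(self, default_geom, rng):
        files = constant_files(default_geom)
        st_res = simulate_stellate_layer(
            files, StellateSampleLaw(), default_geom, rng
        )
        nets = build_pc_afferent_networks(default_geom, rng)
        nets[0].flanks = (nets[0].flanks[0][:3], nets[0].flanks[1])
        with pytest.raises(MolecularError, match="fewer than"):
            integrate_pc(st_res, nets, default_geom, rng)
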