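"""Generator tests: planted populations, EM-CCD renders, substrate kinetics."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from lumitrack.config import (
    ConfigError,
    KineticsConfig,
    MixtureConfig,
    MobilityConfig,
    OpticsConfig,
    PopulationConfig,
)
from lumitrack.presets import load_preset
from lumitrack.simgen import (
    PlacementError,
    render_field,
    sample_population,
    simulate_timecourse,
)


class TestSamplePopulation:
    def test_empty_population(self):
        cfg = PopulationConfig(n_cells=0, field_size=(256, 256))
        assert sample_population(cfg) == []

    def test_all_lost_degenerate_mixture(self):
        cfg = PopulationConfig(
            n_cells=50,
            field_size=(1024, 1024),
            mobility=MobilityConfig(p_lost=1.0),
            seed=3,
        )
        cells = sample_population(cfg)
        assert len(cells) == 50
        assert all(c.fate == "lost" for c in cells)
        assert all(c.pos_t1 is None and c.rate_t1 is None for c in cells)

    def test_reproducible_from_seed(self, small_population):
        a = sample_population(small_population)
        b = sample_population(small_population)
        assert a == b
        c = sample_population(dataclasses.replace(small_population, seed=8))
        assert a != c

    def test_min_separation_and_bounds(self, small_population):
        cells = sample_population(small_population)
        pts = np.array([c.pos_t0 for c in cells])
        d = np.hypot(
            pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1]
        )
        np.fill_diagonal(d, np.inf)
        assert d.min() >= small_population.min_separation
        w, h = small_population.field_size
        m = small_population.margin
        assert pts.min() >= m and pts[:, 0].max() <= w - m and pts[:, 1].max() <= h - m

    def test_field_too_small_raises(self):
        cfg = PopulationConfig(n_cells=500, field_size=(100, 100), min_separation=20)
        with pytest.raises((ConfigError, PlacementError)):
            sample_population(cfg)

    def test_invalid_probabilities_raise(self):
        with pytest.raises(ConfigError):
            PopulationConfig(
                mobility=MobilityConfig(p_lost=0.7, p_displaced=0.5)
            ).validate()
        with pytest.raises(ConfigError):
            PopulationConfig(mixture=MixtureConfig(p_responder=1.5)).validate()

    def test_fate_invariants(self):
        cfg = PopulationConfig(
            n_cells=300,
            field_size=(2048, 2048),
            mobility=MobilityConfig(p_lost=0.2, p_displaced=0.3, jitter_sd=3.0),
            seed=11,
        )
        r = cfg.mobility.match_radius
        for c in sample_population(cfg):
            if c.fate == "lost":
                assert c.pos_t1 is None
            else:
                dx = math.hypot(
                    c.pos_t1[0] - c.pos_t0[0], c.pos_t1[1] - c.pos_t0[1]
                )
                if c.fate == "retained":
                    assert dx <= r
                else:
                    assert dx > r
            assert c.rate_t0 >= 0

    def test_fate_fractions_converge(self):
        p_lost, p_disp = 0.2, 0.3
        cfg = PopulationConfig(
            n_cells=10_000,
            field_size=(8192, 8192),
            min_separation=10.0,
            mobility=MobilityConfig(p_lost=p_lost, p_displaced=p_disp),
            seed=5,
        )
        cells = sample_population(cfg)
        n = len(cells)
        for p, fate in ((p_lost, "lost"), (p_disp, "displaced"), (0.5, "retained")):
            frac = sum(1 for c in cells if c.fate == fate) / n
            assert abs(frac - p) <= 3 * math.sqrt(p * (1 - p) / n)

    def test_responder_fraction_binomial_bound(self):
        cfg = PopulationConfig(
            n_cells=5000,
            field_size=(8192, 8192),
            min_separation=10.0,
            mixture=MixtureConfig(p_responder=0.5),
            seed=2,
        )
        cells = sample_population(cfg)
        frac = sum(1 for c in cells if c.response_class == "responder") / 5000
        assert abs(frac - 0.5) <= 3 * math.sqrt(0.25 / 5000)

    def test_enzalutamide_preset_plants_responder_fraction(self):
        preset = load_preset("lncap_enza", seed=4)
        cells = sample_population(preset.population)
        n = len(cells)
        assert n == 2000
        p = preset.population.mixture.p_responder
        frac = sum(1 for c in cells if c.response_class == "responder") / n
        assert abs(frac - p) <= 1.96 * math.sqrt(p * (1 - p) / n)

    def test_response_class_independent_of_fate(self):
        ok = 0
        for seed in range(20):
            cfg = PopulationConfig(
                n_cells=3000,
                field_size=(8192, 8192),
                min_separation=10.0,
                mixture=MixtureConfig(p_responder=0.4),
                mobility=MobilityConfig(p_lost=0.2, p_displaced=0.3),
                seed=seed,
            )
            cells = sample_population(cfg)
            table = np.zeros((3, 2))
            fates = {"retained": 0, "displaced": 1, "lost": 2}
            for c in cells:
                table[fates[c.fate], int(c.response_class == "responder")] += 1
            _, p, _, _ = chi2_contingency(table)
            ok += p > 0.01
        assert ok >= 19


class TestRenderField:
    def test_background_only_statistics(self, optics):
        img = render_field(
            [], "luminescence", "t0", optics, seed=1, field_size=(512, 512)
        ).astype(float)
        expected_sd = optics.background_pixel_sd
        assert abs(img.mean() - optics.background_level) < 0.5
        assert abs(img.std() - expected_sd) < 0.3

    def test_single_cell_poisson_sum(self):
        optics = OpticsConfig(read_noise_sd=0.0, em_gain=1.0, background_level=0.0)
        cells = sample_population(
            PopulationConfig(
                n_cells=1,
                field_size=(256, 256),
                intensity_lognormal=(math.log(10_000), 0.0),
                seed=9,
            )
        )
        img = render_field(
            cells, "luminescence", "t0", optics, seed=9, field_size=(256, 256)
        )
        assert abs(float(img.sum()) - 10_000) <= 3 * math.sqrt(10_000)

    def test_noise_free_flux_conservation(self):
        """Integrated intensity of an isolated cell = rate x em_gain (<0.5% off)."""
        optics = OpticsConfig(em_gain=2.0)
        cells = sample_population(
            PopulationConfig(
                n_cells=1,
                field_size=(128, 128),
                intensity_lognormal=(math.log(5000), 0.0),
                seed=1,
            )
        )
        img = render_field(
            cells, "luminescence", "t0", optics, seed=1,
            field_size=(128, 128), noise=False,
        )
        total = float(img.sum()) - optics.background_level * img.size
        assert abs(total - 5000 * optics.em_gain) / (5000 * optics.em_gain) < 0.005

    def test_saturation_clipping(self):
        optics = OpticsConfig(saturation=65535)
        cells = sample_population(
            PopulationConfig(
                n_cells=1,
                field_size=(128, 128),
                intensity_lognormal=(math.log(1e9), 0.0),
                seed=1,
            )
        )
        img = render_field(
            cells, "luminescence", "t0", optics, seed=1, field_size=(128, 128)
        )
        assert int(img.max()) == 65535

    def test_unknown_channel_or_timepoint(self, optics):
        with pytest.raises(ValueError):
            render_field([], "brightfield", "t0", optics, 1, (64, 64))
        with pytest.raises(ValueError):
            render_field([], "luminescence", "t2", optics, 1, (64, 64))

    def test_render_reproducible(self, optics, small_population):
        cells = sample_population(small_population)
        a = render_field(cells, "fluorescence", "t0", optics, 5, (640, 640))
        b = render_field(cells, "fluorescence", "t0", optics, 5, (640, 640))
        assert np.array_equal(a, b)


class TestTimecourse:
    def test_no_decay_noise_free_constant(self):
        df = simulate_timecourse(1234.0, KineticsConfig(decay_rate=0.0), 1, noise=False)
        assert np.allclose(df["intensity"], 1234.0)
        assert df["time_min"].iloc[0] == 30.0 and df["time_min"].iloc[-1] == 230.0

    def test_half_life_arithmetic(self):
        k = KineticsConfig(decay_rate=math.log(2) / 100.0)
        df = simulate_timecourse(1000.0, k, 1, noise=False)
        at = lambda t: float(df.loc[df.time_min == t, "intensity"].iloc[0])
        assert at(130.0) / at(30.0) == pytest.approx(0.5, rel=1e-12)

    def test_monte_carlo_mean_matches_closed_form(self):
        k = KineticsConfig(decay_rate=0.01)
        rate0 = 20_000.0
        acc = None
        n_rep = 1000
        for s in range(n_rep):
            df = simulate_timecourse(rate0, k, seed=s)
            acc = df["intensity"].to_numpy() if acc is None else acc + df["intensity"].to_numpy()
        mean = acc / n_rep
        t = df["time_min"].to_numpy()
        expected = rate0 * np.exp(-k.decay_rate * (t - k.t_start))
        assert np.all(np.abs(mean - expected) / expected < 0.01)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_timecourse(-1.0, KineticsConfig(), 1)
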