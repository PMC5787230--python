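"""Panel formats, fixture generator, trend fitting, ROH class tables."""

import numpy as np
import pandas as pd
import pytest

from rohsim import panel_io as pio


@pytest.fixture()
def small_panel(rng=None):
    rng = np.random.default_rng(0)
    n, m = 10, 40
    dose = rng.integers(0, 3, (n, m)).astype(np.int8)
    dose[0, 0] = -1
    dose[3, 7] = -1
    snp_map = pd.DataFrame(
        {
            "chrom": np.repeat([1, 2], m // 2),
            "snp_id": [f"snp{i}" for i in range(m)],
            "cm": np.tile(np.arange(m // 2) * 0.05, 2),
            "bp": np.tile(np.arange(1, m // 2 + 1) * 50_000, 2),
        }
    )
    samples = pd.DataFrame(
        {
            "fid": 1,
            "iid": [f"A{i}" for i in range(n)],
            "sire": 0,
            "dam": 0,
            "sex": [1, 2] * (n // 2),
            "phen": -9,
        }
    )
    return pio.Panel(dose, snp_map, samples)


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["ped", "bed"])
    def test_write_read_identical(self, small_panel, tmp_path, fmt):
        prefix = str(tmp_path / "panel")
        pio.write_panel(small_panel, prefix, fmt=fmt)
        back = pio.read_panel(prefix, fmt=fmt)
        assert np.array_equal(back.dose, small_panel.dose)
        assert back.snp_map["bp"].tolist() == small_panel.snp_map["bp"].tolist()
        assert back.samples["iid"].tolist() == small_panel.samples["iid"].tolist()

    def test_dialect_equivalence(self, small_panel, tmp_path):
        pa, pb = str(tmp_path / "a"), str(tmp_path / "b")
        pio.write_panel(small_panel, pa, fmt="ped")
        pio.write_panel(small_panel, pb, fmt="bed")
        assert np.array_equal(pio.read_panel(pa).dose, pio.read_panel(pb).dose)

    def test_truncated_bed_names_offset(self, small_panel, tmp_path):
        prefix = str(tmp_path / "trunc")
        pio.write_panel(small_panel, prefix, fmt="bed")
        raw = open(prefix + ".bed", "rb").read()
        open(prefix + ".bed", "wb").write(raw[:-5])
        with pytest.raises(ValueError, match="byte offset"):
            pio.read_panel(prefix)

    def test_dimension_mismatch_rejected(self, small_panel):
        with pytest.raises(ValueError, match="inconsistent"):
            pio.Panel(small_panel.dose[:, :-1], small_panel.snp_map, small_panel.samples)


def _small_fixture_config(**kw):
    base = dict(
        year_start=2000, year_end=2011, changepoint_year=2008,
        animals_per_year=60, n_chrom=5, total_cm=500.0, n_snp=9000,
        n_founders=120, slope_pre=0.002, slope_post=0.010,
    )
    base.update(kw)
    return pio.PanelFixtureConfig(**base)


@pytest.fixture(scope="module")
def fixture_run():
    return pio.generate_panel_fixture(_small_fixture_config(), rng=42)


class TestFixture:
    def test_bookkeeping_counts(self, fixture_run):
        cfg = fixture_run.config
        n_total = cfg.n_founders + 12 * cfg.animals_per_year
        assert fixture_run.panel.dose.shape == (n_total, cfg.n_snp)
        assert len(fixture_run.pedigree) == n_total

    def test_two_slope_recovery(self, fixture_run):
        """Fitted F_ROH slopes recover the configured trend."""
        cfg = fixture_run.config
        born = fixture_run.birth_year >= cfg.year_start
        rep = pio.annual_trend(
            fixture_run.f_roh[born], fixture_run.birth_year[born], cfg.changepoint_year
        )
        assert rep.slope_post > rep.slope_pre
        assert abs(rep.slope_pre - cfg.slope_pre) < max(2 * rep.se_pre, 0.5 * cfg.slope_pre)
        assert abs(rep.slope_post - cfg.slope_post) < max(2 * rep.se_post, 0.5 * cfg.slope_post)

    def test_length_distribution_right_skewed(self, fixture_run):
        seg = fixture_run.segments
        span_mb = (seg.end_bp - seg.start_bp + 1) / 1e6
        assert span_mb.mean() > span_mb.median()  # right skew: short segments dominate

    def test_flat_trend_with_zero_slopes(self):
        # a flat trend needs enough parental diversity that the drift floor
        # stays well below the trend scale over the span
        cfg = _small_fixture_config(
            slope_pre=0.0, slope_post=0.0, animals_per_year=80, n_founders=200,
            parent_depth=3, year_end=2009, n_snp=3000,
        )
        fx = pio.generate_panel_fixture(cfg, rng=7)
        born = fx.birth_year >= cfg.year_start
        rep = pio.annual_trend(fx.f_ped[born], fx.birth_year[born], cfg.changepoint_year)
        assert abs(rep.slope_pre) < 0.002 and abs(rep.slope_post) < 0.004

    def test_unattainable_slopes_rejected(self):
        with pytest.raises(ValueError):
            _small_fixture_config(slope_post=0.2).validate()


class TestAnnualTrend:
    def test_exact_line_recovered(self):
        years = np.repeat(np.arange(2000, 2010), 5)
        f = 0.005 * (years - 2000)
        rep = pio.annual_trend(f, years, changepoint=2005)
        assert rep.slope_pre == pytest.approx(0.005)
        assert rep.slope_post == pytest.approx(0.005)
        assert rep.se_pre == pytest.approx(0.0, abs=1e-12)

    def test_single_year_period_missing(self):
        years = np.array([2000, 2001, 2002, 2003, 2010])
        f = np.linspace(0, 0.02, 5)
        rep = pio.annual_trend(f, years, changepoint=2009)
        assert np.isnan(rep.slope_post)
        assert np.isfinite(rep.slope_pre)


class TestRohClassesAndCurve:
    def _segments(self):
        # spans: 1.5, 3, 5, 12, 20 Mb
        mb = np.array([1.5, 3, 5, 12, 20])
        return pd.DataFrame(
            {
                "animal": [1, 1, 1, 2, 2],
                "chrom": [1, 2, 3, 1, 2],
                "start_idx": 0,
                "end_idx": 10,
                "start_bp": 1,
                "end_bp": (mb * 1e6).astype(int),
                "n_snp": [30, 60, 100, 240, 400],
                "n_het": 0,
            }
        )

    def test_class_frequencies_partition(self):
        out = pio.roh_class_table(self._segments())
        assert out["frequency"].sum() == pytest.approx(1.0)
        assert out["count"].tolist() == [1, 1, 1, 1, 1]

    def test_single_class_holds_everything(self):
        seg = self._segments().iloc[:1]
        out = pio.roh_class_table(seg)
        assert out["frequency"].iloc[0] == pytest.approx(1.0)

    def test_overlapping_classes_rejected(self):
        with pytest.raises(ValueError):
            pio.roh_class_table(self._segments(), classes_mb=((0, 4), (2, float("inf"))))

    def test_cumulative_curve_terminal_equals_f_roh(self):
        from rohsim import inbreeding as ib

        seg = self._segments()
        curve = pio.cumulative_roh_curve(seg, n_snp_total=10_000, n_animals=2,
                                         length_grid_mb=np.array([2.0, 10.0, 50.0]))
        assert (np.diff(curve.mean_count) >= 0).all()
        f = ib.f_roh(seg, np.array([1, 2]), 10_000)
        assert curve.mean_f_roh.iloc[-1] == pytest.approx(f.mean())

    def test_curve_steps_at_segment_length(self):
        seg = self._segments().iloc[2:3]  # one 5 Mb segment
        curve = pio.cumulative_roh_curve(seg, 1000, 1, np.array([4.0, 5.0, 6.0]))
        assert curve.mean_count.tolist() == [0.0, 1.0, 1.0]
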