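"""Synthetic sites and networks: ground truth, determinism, round trips."""

import json

import numpy as np
import pandas as pd
import pytest

from fluxresp import (
    NetworkConfig,
    SyntheticSiteConfig,
    generate_monotone_site,
    generate_network,
    generate_site,
    read_site_csv,
    site_pipeline,
    tent_response,
    write_network,
    write_site_csv,
)
from fluxresp.errors import InfeasibleConfoundError, InputError


class TestGenerateSite:
    def test_noise_free_limit_is_exact_tent(self, config):
        cfg = SyntheticSiteConfig(noise_sd_log=0.0, q10=1.0, confound_r=0.0, seed=1)
        site, truth = generate_site(cfg)
        d = site.data
        expected = tent_response(d["sm"], 25.0, 8.0, 0.30, 0.15)
        assert np.allclose(d["er"], expected, atol=1e-12)

    def test_noise_free_symmetric_tent_recovered_to_bin_scale(self, config):
        # a symmetric apex is preserved by the spline smooth; the asymmetric
        # case shifts it slightly toward the flatter side (see methods note)
        cfg = SyntheticSiteConfig(
            noise_sd_log=0.0, q10=1.0, confound_r=0.0, seed=1,
            slope_below=0.30, slope_above=0.30,
        )
        site, _ = generate_site(cfg)
        _, res = site_pipeline(site, config)
        assert res.detected
        assert abs(res.smer_opt - 25.0) <= 3 * config.bin_width

    def test_envelope_peaks_at_true_optimum(self, default_site):
        """Brute-force upper envelope of the raw data peaks near the truth."""
        site, truth = default_site
        d = site.data
        edges = np.arange(5, 46, 1.0)
        env = [
            np.quantile(d.loc[(d.sm >= lo) & (d.sm < lo + 1), "er"], 0.95)
            for lo in edges[:-1]
            if ((d.sm >= lo) & (d.sm < lo + 1)).sum() > 50
        ]
        peak_sm = edges[int(np.argmax(env))] + 0.5
        assert abs(peak_sm - truth["true_opt"]) <= 2.0

    def test_same_seed_identical(self):
        a, _ = generate_site(SyntheticSiteConfig(seed=5))
        b, _ = generate_site(SyntheticSiteConfig(seed=5))
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_bounds_and_signs(self, default_site):
        site, _ = default_site
        d = site.data
        assert d["sm"].between(0, 100).all()
        assert (d["er"] >= 0).all()
        assert (d["isr"] >= 0).all()
        assert (d["vpd"] > 0).all()
        assert (d["er_qc"] == 0).all()

    def test_optimum_outside_range_rejected(self):
        with pytest.raises(InputError, match="outside generated SM range"):
            generate_site(SyntheticSiteConfig(true_opt=70.0, seed=0))

    @pytest.mark.parametrize("r", [0.0, 0.4, -0.3])
    def test_confounder_correlation_targets(self, r):
        _, truth = generate_site(SyntheticSiteConfig(seed=13, confound_r=r))
        assert abs(truth["corr_sm_tair"] - r) <= 0.05
        assert abs(truth["corr_sm_vpd"] - r) <= 0.05
        assert abs(truth["corr_sm_cloud_driver"] - r) <= 0.05

    def test_infeasible_confound_raises(self):
        with pytest.raises(InfeasibleConfoundError):
            generate_site(SyntheticSiteConfig(seed=0, confound_r=0.9))


class TestMonotoneSite:
    def test_truncated_marks_no_optimum(self):
        site, truth = generate_monotone_site(SyntheticSiteConfig(seed=3), mode="truncated")
        assert np.isnan(truth["true_opt"])
        assert truth["tent_apex"] > site.data["sm"].max()

    def test_plateau_response_is_flat_above(self):
        cfg = SyntheticSiteConfig(seed=3, noise_sd_log=0.0, q10=1.0)
        site, truth = generate_monotone_site(cfg, mode="plateau")
        d = site.data
        above = d.loc[d.sm > 26, "er"]
        assert above.std() == pytest.approx(0.0, abs=1e-9)

    def test_full_range_control_from_same_seed_detects(self, config):
        """Paired contrast: same seed detects normally but not truncated."""
        cfg = SyntheticSiteConfig(seed=17)
        full, _ = generate_site(cfg)
        trunc, _ = generate_monotone_site(cfg, mode="truncated")
        _, res_full = site_pipeline(full, config)
        _, res_trunc = site_pipeline(trunc, config)
        assert res_full.detected
        assert not res_trunc.detected

    def test_unknown_mode_rejected(self):
        with pytest.raises(InputError):
            generate_monotone_site(SyntheticSiteConfig(seed=0), mode="wiggly")


@pytest.fixture(scope="module")
def tiny_network():
    net = NetworkConfig(
        n_sites=6,
        seed=21,
        site_template=SyntheticSiteConfig(n_records=4000),
    )
    return generate_network(net)


class TestGenerateNetwork:
    def test_structure(self, tiny_network):
        assert len(tiny_network.sites) == 6
        assert len(tiny_network.covariates) == 6
        assert len(tiny_network.truth) == 6
        assert set(tiny_network.covariates.columns) >= {
            "site_id", "igbp", "sm_growth", "tem", "isr", "vpd", "st", "pre",
            "lai", "bd", "soc", "cec", "ph", "sand",
        }
        assert tiny_network.covariates.notna().all().all()

    def test_optima_follow_linear_law_with_scatter(self):
        net = NetworkConfig(n_sites=40, seed=2,
                            site_template=SyntheticSiteConfig(n_records=1000))
        result = generate_network(net)
        t = result.truth
        resid = t["true_opt"] - (3.0 + 0.86 * t["sm_growth_target"])
        assert abs(resid.mean()) < 1.5
        assert 1.5 < resid.std() < 5.0

    def test_optima_interior_to_site_ranges(self, tiny_network):
        t = tiny_network.truth
        assert (t["true_opt"] > t["sm_min"]).all()
        assert (t["true_opt"] < t["sm_max"]).all()

    def test_null_network(self):
        net = NetworkConfig(n_sites=5, cross_slope=0.0, seed=9,
                            site_template=SyntheticSiteConfig(n_records=1000))
        t = generate_network(net).truth
        assert abs(np.corrcoef(t["sm_growth_target"], t["true_opt"])[0, 1]) < 0.9


class TestWriteReadRoundTrip:
    def test_site_csv_round_trip(self, tmp_path, tiny_network):
        site = tiny_network.sites[0]
        path = tmp_path / "site.csv"
        write_site_csv(site, path)
        back = read_site_csv(path, site_id=site.site_id)
        for col in ("er", "sm", "gpp", "isr", "tair", "vpd"):
            assert np.allclose(back.data[col], site.data[col], atol=1e-5)
        assert (back.data["timestamp"] == site.data["timestamp"]).all()

    def test_network_manifest_deterministic(self, tmp_path, tiny_network):
        m1 = write_network(tiny_network, tmp_path / "a", seed=21)
        m2 = write_network(tiny_network, tmp_path / "b", seed=21)
        assert m1["sha256"] == m2["sha256"]
        assert m1["n_sites"] == 6

    def test_refuses_nonempty_dir(self, tmp_path, tiny_network):
        out = tmp_path / "net"
        write_network(tiny_network, out, seed=21)
        with pytest.raises(InputError, match="force"):
            write_network(tiny_network, out, seed=21)
        write_network(tiny_network, out, seed=21, force=True)  # ok

    def test_truth_round_trips_generator_parameters(self, tmp_path, tiny_network):
        out = tmp_path / "net2"
        write_network(tiny_network, out, seed=21)
        truth = pd.read_csv(out / "truth.csv")
        row = truth.iloc[0]
        regenerated, _ = generate_site(
            SyntheticSiteConfig(
                n_records=int(row["n_records"]),
                sm_mean=row["sm_mean"], sm_span=row["sm_span"],
                sm_seasonal_amp=row["sm_seasonal_amp"], sm_ar1=row["sm_ar1"],
                sm_noise_sd=row["sm_noise_sd"], sm_phase_doy=row["sm_phase_doy"],
                true_opt=row["true_opt"], er_max=row["er_max"],
                slope_below=row["slope_below"], slope_above=row["slope_above"],
                q10=row["q10"], t_ref=row["t_ref"],
                noise_sd_log=row["noise_sd_log"], confound_r=row["confound_r"],
                gpp_max=row["gpp_max"], start=row["start"], seed=int(row["seed"]),
            ),
            site_id=row["site_id"],
        )
        original = tiny_network.sites[0]
        pd.testing.assert_frame_equal(regenerated.data, original.data)

    def test_manifest_file_lists_all_sites(self, tmp_path, tiny_network):
        out = tmp_path / "net3"
        manifest = write_network(tiny_network, out, seed=21)
        listed = json.loads((out / "manifest.json").read_text())
        assert listed["files"] == manifest["files"]
        assert sum(1 for f in listed["files"] if f.startswith("SYN-")) == 6
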