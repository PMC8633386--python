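import dataclasses

import numpy as np
import pytest

from metamel.analysis import (
    build_atlas,
    cct_summaries_to_csv,
    delta_e_at_lux,
    michelson_contrast,
    summaries_from_csv,
    summaries_to_csv,
    summarize_cct,
    summarize_target,
    TargetSummary,
)
from metamel.colorimetry import SpectrumMetrics
from metamel.grid import ChromaticityTarget
from metamel.optimizer import MetamerRecord, MetamerSet


class TestMichelsonContrast:
    @pytest.mark.parametrize(
        "pair, expected",
        [((181.0, 271.0), 0.20), ((135.0, 185.0), 0.16), ((115.0, 165.0), 0.18)],
    )
    def test_worked_pairs_to_two_decimals(self, pair, expected):
        assert round(michelson_contrast(*pair), 2) == expected

    def test_exact_value(self):
        assert michelson_contrast(135.0, 185.0) == pytest.approx(0.15625)

    def test_equal_pair_is_zero(self):
        assert michelson_contrast(100.0, 100.0) == 0.0

    def test_scale_invariance_and_monotonicity(self, rng):
        lo, hi = 120.0, 260.0
        assert michelson_contrast(3 * lo, 3 * hi) == pytest.approx(
            michelson_contrast(lo, hi)
        )
        assert michelson_contrast(lo, hi + 10.0) > michelson_contrast(lo, hi)

    def test_errors(self):
        with pytest.raises(ValueError):
            michelson_contrast(0.0, 0.0)
        with pytest.raises(ValueError):
            michelson_contrast(200.0, 100.0)


class TestDeltaEAtLux:
    @pytest.mark.parametrize(
        "dg, ev, expected", [(0.236, 250.0, 59.0), (0.25, 250.0, 62.5),
                             (0.123, 0.0, 0.0)]
    )
    def test_products(self, dg, ev, expected):
        assert delta_e_at_lux(dg, ev) == pytest.approx(expected, abs=0.5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            delta_e_at_lux(-0.1, 250.0)


def synthetic_set(target, e_mels, e_v=250.0):
    members = []
    for e_mel in e_mels:
        metrics = SpectrumMetrics(
            e_v=e_v, e_mel=e_mel, gamma_mel=e_mel / e_v,
            x=target.x, y=target.y,
            u_prime=target.u_prime, v_prime=target.v_prime,
            cct=target.cct, duv=target.duv,
        )
        members.append(MetamerRecord(
            weights=np.zeros(3), spectrum=None, metrics=metrics,
        ))
    return MetamerSet(target=target, members=tuple(members),
                      output_illuminance=e_v)


def make_target(cct=5552.0, duv=0.021, level=(3, 7)):
    from metamel.grid import duv_offset, planck_point

    chrom = duv_offset(planck_point(cct), duv)
    return ChromaticityTarget(
        cct=cct, duv=duv, u_prime=chrom.u_prime, v_prime=chrom.v_prime,
        x=chrom.x, y=chrom.y, cct_level=level[0], duv_level=level[1],
    )


class TestSummarizeTarget:
    def test_worked_example_extremes(self):
        ms = synthetic_set(make_target(), [212.0, 181.0, 240.0, 271.0])
        s = summarize_target(ms)
        assert s.e_mel_min == 181.0 and s.e_mel_max == 271.0
        assert s.delta_e_mel == pytest.approx(90.0)
        assert round(s.c_m, 2) == 0.20
        assert s.delta_gamma == pytest.approx(90.0 / 250.0)
        assert s.delta_e_mel == pytest.approx(250.0 * s.delta_gamma)

    def test_singleton(self):
        s = summarize_target(synthetic_set(make_target(), [200.0]))
        assert s.delta_e_mel == 0.0 and s.delta_gamma == 0.0 and s.c_m == 0.0

    def test_empty_sentinel(self):
        assert summarize_target(synthetic_set(make_target(), [])) is None

    def test_extremes_match_exhaustive_scan(self, rng):
        e_mels = list(rng.uniform(100.0, 350.0, 100))
        s = summarize_target(synthetic_set(make_target(), e_mels))
        assert s.e_mel_min == min(e_mels) and s.e_mel_max == max(e_mels)
        assert s.n_metamers == 100


class TestSummarizeCct:
    def test_independent_argmaxes(self):
        # one Duv offers the largest DER, another the largest tuning range
        t1 = make_target(2901.0, -0.039, level=(1, -13))
        t2 = make_target(2901.0, -0.018, level=(1, -6))
        s1 = summarize_target(synthetic_set(t1, [126.0, 185.0]))  # max 0.74
        s2 = summarize_target(synthetic_set(t2, [100.0, 172.5]))  # dg 0.29
        cs = summarize_cct([s1, s2])
        assert cs.gamma_hat_max == pytest.approx(0.74)
        assert cs.duv_at_gamma_max == -0.039
        assert cs.delta_gamma_tilde == pytest.approx(0.29)
        assert cs.duv_at_delta_gamma == -0.018

    def test_single_group(self):
        s = summarize_target(synthetic_set(make_target(), [150.0, 250.0]))
        cs = summarize_cct([s])
        assert cs.gamma_hat_min == s.gamma_min
        assert cs.gamma_hat_max == s.gamma_max
        assert cs.delta_gamma_tilde == s.delta_gamma

    def test_matches_brute_force_group_scan(self, rng):
        summaries = []
        for duv_level in range(-5, 6):
            t = make_target(4000.0, duv_level * 0.003, level=(2, duv_level))
            e_mels = list(rng.uniform(80.0, 320.0, 20))
            summaries.append(summarize_target(synthetic_set(t, e_mels)))
        cs = summarize_cct(summaries)
        assert cs.gamma_hat_min == min(s.gamma_min for s in summaries)
        assert cs.gamma_hat_max == max(s.gamma_max for s in summaries)
        assert cs.delta_gamma_tilde == max(s.delta_gamma for s in summaries)

    def test_empty_and_mixed_levels(self):
        assert summarize_cct([None, None]) is None
        a = summarize_target(synthetic_set(make_target(level=(1, 0)), [150.0]))
        b = summarize_target(synthetic_set(make_target(level=(2, 0)), [150.0]))
        with pytest.raises(ValueError):
            summarize_cct([a, b])


def lattice_summaries(values):
    """Summaries on a 3x3 xy lattice with prescribed delta_gamma values."""
    out = []
    xs = ys = [0.30, 0.35, 0.40]
    k = 0
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            t = ChromaticityTarget(
                cct=3000.0 + 100 * k, duv=0.0, u_prime=0.2, v_prime=0.45,
                x=x, y=y, cct_level=i, duv_level=j,
            )
            dg = values[k]
            e_min = 100.0
            e_max = e_min + dg * 250.0
            out.append(TargetSummary(
                target=t, n_metamers=5, e_mel_min=e_min, e_mel_max=e_max,
                delta_e_mel=e_max - e_min, gamma_min=e_min / 250.0,
                gamma_max=e_max / 250.0, delta_gamma=dg,
                c_m=michelson_contrast(e_min, e_max),
            ))
            k += 1
    return out


class TestAtlas:
    def test_node_exactness_on_aligned_raster(self, rng):
        values = list(rng.uniform(0.05, 0.4, 9))
        summaries = lattice_summaries(values)
        atlas = build_atlas(summaries, resolution=3)
        # resolution 3 puts raster nodes exactly on the target lattice
        field = atlas.delta_gamma_field.T.ravel()  # x fast index -> transpose
        assert np.allclose(np.sort(field), np.sort(values), atol=1e-9)

    def test_global_max_is_brute_force_max(self, rng):
        values = list(rng.uniform(0.05, 0.4, 9))
        atlas = build_atlas(lattice_summaries(values), resolution=10)
        assert atlas.max_delta_gamma.delta_gamma == max(values)
        assert np.nanmax(atlas.delta_gamma_field) <= max(values) + 1e-12

    def test_constant_field(self):
        atlas = build_atlas(lattice_summaries([0.2] * 9), resolution=8)
        fld = atlas.delta_gamma_field
        assert np.allclose(fld[~np.isnan(fld)], 0.2)

    def test_tie_break_lowest_index(self):
        values = [0.2, 0.3, 0.2, 0.3, 0.1, 0.1, 0.05, 0.05, 0.05]
        atlas = build_atlas(lattice_summaries(values), resolution=5)
        assert atlas.max_delta_gamma.target.index == (0, 1)

    def test_insufficient_targets(self):
        with pytest.raises(ValueError):
            build_atlas(lattice_summaries([0.1] * 9)[:2])

    def test_collinear_targets(self):
        summaries = [
            s for s in lattice_summaries([0.1] * 9)
            if s.target.x == 0.30
        ]
        with pytest.raises(ValueError):
            build_atlas(summaries)

    def test_export_and_round_trip(self, tmp_path, rng):
        values = list(rng.uniform(0.05, 0.4, 9))
        atlas = build_atlas(lattice_summaries(values), luminaire="8ch",
                            criterion="p3", resolution=6)
        atlas.to_dir(tmp_path)
        back = summaries_from_csv(tmp_path / "target_summaries.csv")
        assert len(back) == 9
        assert back[0].delta_gamma == pytest.approx(
            atlas.summaries[0].delta_gamma
        )
        import json

        payload = json.loads((tmp_path / "atlas.json").read_text())
        assert payload["max_delta_gamma"]["value"] == pytest.approx(max(values))
        cct_summaries_to_csv(tmp_path / "cct.csv", atlas.cct_summaries)
        assert (tmp_path / "cct.csv").exists()

    def test_plot_export(self, tmp_path, rng):
        atlas = build_atlas(
            lattice_summaries(list(rng.uniform(0.1, 0.3, 9))), resolution=6
        )
        atlas.plot(tmp_path / "map.png")
        assert (tmp_path / "map.png").stat().st_size > 0
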