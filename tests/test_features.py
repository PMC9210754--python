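"""The 13 window features, checked against independent oracles."""

import cmath

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fogsense as fs
from fogsense.channels import ChannelSpec
from fogsense.features import FEATURE_NAMES, FI_EPS
from fogsense.windows import WindowSet


def dft_band_power_oracle(x, band, fs_hz, right_open=False):
    """Brute-force O(N^2) two-sided DFT band power, scaled by 1/N."""
    n = len(x)
    total = 0.0
    for k in range(n):
        f = k * fs_hz / n
        if f > fs_hz / 2:
            f -= fs_hz
        af = abs(f)
        in_band = band[0] <= af and (af < band[1] if right_open else af <= band[1])
        if not in_band:
            continue
        xk = sum(x[m] * cmath.exp(-2j * cmath.pi * k * m / n) for m in range(n))
        total += abs(xk) ** 2
    return total / n


def make_windowset(windows_by_channel, fs_hz=100.0, labels=None):
    """windows_by_channel: dict channel -> (n_w, L) array."""
    chans = list(windows_by_channel)
    arrs = np.stack([windows_by_channel[c] for c in chans], axis=1)
    n_w = arrs.shape[0]
    return WindowSet(
        arrs,
        np.zeros(n_w, dtype=np.uint8) if labels is None else np.asarray(labels),
        np.full(n_w, "T", dtype=object),
        np.arange(n_w) * 0.5,
        fs_hz,
        arrs.shape[2] / fs_hz,
        0.5,
        chans,
    )


CH_X = ChannelSpec("left_shank", "gyroscope", "x")
CH_Y = ChannelSpec("left_shank", "gyroscope", "y")
CH_Z = ChannelSpec("left_shank", "gyroscope", "z")
T200 = np.arange(200) / 100.0


class TestBandPower:
    def test_pure_tone_lands_in_freeze_zone(self):
        x = np.sin(2 * np.pi * 6 * T200)
        freeze = fs.band_power(x, (3, 8), 100.0)
        total_nondc = fs.band_power(x, (0.01, 50), 100.0)
        assert freeze >= 0.99 * total_nondc > 0

    def test_zero_vector(self):
        assert fs.band_power(np.zeros(100), (3, 8), 100.0) == 0.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=64)
        for band, ro in [((0.5, 3.0), True), ((3.0, 8.0), False), ((10.0, 20.0), False)]:
            np.testing.assert_allclose(
                fs.band_power(x, band, 100.0, right_open=ro),
                dft_band_power_oracle(x, band, 100.0, right_open=ro),
                rtol=1e-9,
            )

    def test_parseval(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=128)
        band_total = fs.band_power(x, (1e-9, 50.0), 100.0)
        dc = abs(x.sum()) ** 2 / len(x)
        np.testing.assert_allclose(band_total + dc, (x**2).sum(), rtol=1e-9)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(fs.DataError):
            fs.band_power(np.ones(10), (10.0, 60.0), 100.0)


class TestFreezeIndex:
    def test_tone_discrimination(self):
        """6 Hz tone -> FI huge; 1.5 Hz tone -> FI tiny (brute-force bands)."""
        fog = np.sin(2 * np.pi * 6 * T200)
        walk = np.sin(2 * np.pi * 1.5 * T200)
        for x, check in [(fog, lambda v: v >= 50), (walk, lambda v: v <= 0.02)]:
            freeze = dft_band_power_oracle(x, (3, 8), 100.0)
            motion = dft_band_power_oracle(x, (0.5, 3), 100.0, right_open=True)
            assert check(freeze / (motion + FI_EPS))
            ws = make_windowset({CH_X: x[None, :]})
            table = fs.compute_features(ws)
            fi = table.values[0, table.column_names.index(f"{CH_X.name}__fi")]
            assert check(fi)

    def test_fog_windows_have_higher_fi(self, shank_table):
        """The freeze-index premise on synthetic data: FI separates classes."""
        col = shank_table.column_names.index("left_shank_gyroscope_x__fi")
        fog = shank_table.labels == 1
        assert fog.any() and (~fog).any()
        assert (
            shank_table.values[fog, col].mean()
            > shank_table.values[~fog, col].mean()
        )


class TestFeatureValues:
    def test_column_count_and_order(self):
        rng = np.random.default_rng(0)
        ws = make_windowset({c: rng.normal(size=(3, 200)) for c in (CH_X, CH_Y)})
        table = fs.compute_features(ws)
        assert table.n_features == 26
        assert table.column_names[:2] == [f"{CH_X.name}__fi", f"{CH_X.name}__energy"]
        assert [n for _, n in table.feature_ids[:13]] == list(FEATURE_NAMES)

    def test_full_montage_624_columns(self):
        rng = np.random.default_rng(1)
        ws = make_windowset({c: rng.normal(size=(2, 200)) for c in fs.full_montage()})
        assert fs.compute_features(ws).n_features == 624

    def test_constant_window_degenerates(self):
        c = -3.7
        ws = make_windowset({CH_X: np.full((1, 200), c)})
        row = dict(zip(fs.compute_features(ws).column_names,
                       fs.compute_features(ws).values[0]))
        pre = CH_X.name
        assert row[f"{pre}__mean"] == pytest.approx(c)
        assert row[f"{pre}__abs_mean"] == pytest.approx(abs(c))
        assert row[f"{pre}__std"] == pytest.approx(0, abs=1e-12)
        assert row[f"{pre}__range"] == 0
        assert row[f"{pre}__rms"] == pytest.approx(abs(c))
        assert row[f"{pre}__max"] == row[f"{pre}__min"] == pytest.approx(c)
        assert row[f"{pre}__zcr"] == 0 and row[f"{pre}__entropy"] == 0

    def test_zero_crossing_zero_inheritance(self):
        # a zero sample inherits the previous sign: [1, 0, -1] crosses once
        ws = make_windowset(
            {CH_X: np.array([[1.0, 0.0, -1.0, 1.0], [1.0, 0.0, 1.0, 1.0]])}
        )
        table = fs.compute_features(ws)
        zcr = table.values[:, table.column_names.index(f"{CH_X.name}__zcr")]
        np.testing.assert_array_equal(zcr, [2.0, 0.0])

    def test_entropy_two_level_window(self):
        x = np.array([[0.0] * 100 + [1.0] * 100])
        table = fs.compute_features(make_windowset({CH_X: x}))
        ent = table.values[0, table.column_names.index(f"{CH_X.name}__entropy")]
        assert ent == pytest.approx(np.log(2))

    def test_principal_eigenvalues_triaxial(self):
        rng = np.random.default_rng(7)
        wins = {c: rng.normal(size=(4, 100)) for c in (CH_X, CH_Y, CH_Z)}
        table = fs.compute_features(make_windowset(wins))
        for w in range(4):
            x = np.stack([wins[c][w] for c in (CH_X, CH_Y, CH_Z)])
            expected = np.sort(np.linalg.eigvalsh(np.cov(x, bias=True)))[::-1]
            got = [
                table.values[w, table.column_names.index(f"{c.name}__pde")]
                for c in (CH_X, CH_Y, CH_Z)
            ]
            np.testing.assert_allclose(got, expected, rtol=1e-9)

    def test_principal_eigenvalue_single_channel_is_variance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(2, 150))
        chan = ChannelSpec("left_sole_1", "fsr", "none")
        table = fs.compute_features(make_windowset({chan: x}))
        pde = table.values[:, table.column_names.index(f"{chan.name}__pde")]
        np.testing.assert_allclose(pde, x.var(axis=1), rtol=1e-9)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(scale=st.floats(0.1, 50.0), seed=st.integers(0, 100))
    def test_scale_covariance(self, scale, seed):
        """a*x: energy scales a^2; rms/std/range scale a; FI and ZCR fixed."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(1, 200))
        t1 = fs.compute_features(make_windowset({CH_X: x}))
        t2 = fs.compute_features(make_windowset({CH_X: scale * x}))
        cols = {n: t1.column_names.index(f"{CH_X.name}__{n}") for n in FEATURE_NAMES}
        v1, v2 = t1.values[0], t2.values[0]
        np.testing.assert_allclose(v2[cols["energy"]], scale**2 * v1[cols["energy"]], rtol=1e-9)
        for n in ("rms", "std", "range"):
            np.testing.assert_allclose(v2[cols[n]], scale * v1[cols[n]], rtol=1e-9)
        np.testing.assert_allclose(v2[cols["fi"]], v1[cols["fi"]], rtol=1e-6)
        assert v2[cols["zcr"]] == v1[cols["zcr"]]


class TestMinMax:
    def test_printed_transform(self, random_table):
        tbl = random_table.select_columns([0, 1, 2])
        tbl.values[:3, 0] = [2.0, 4.0, 6.0]
        model = fs.fit_minmax(tbl.select_rows(np.arange(3)))
        out = fs.apply_minmax(model, tbl.select_rows(np.arange(3)))
        np.testing.assert_allclose(out.values[:, 0], [0.0, 0.5, 1.0])

    def test_self_application_in_unit_interval(self, random_table):
        out = fs.apply_minmax(fs.fit_minmax(random_table), random_table)
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0

    def test_constant_feature_maps_to_zero(self, random_table):
        tbl = random_table.select_columns([0, 1])
        tbl.values[:, 1] = 9.9
        out = fs.apply_minmax(fs.fit_minmax(tbl), tbl)
        np.testing.assert_array_equal(out.values[:, 1], 0.0)

    def test_test_values_not_clipped(self, random_table):
        train = random_table.select_rows(np.arange(100))
        test = random_table.select_rows(np.arange(100, 200))
        out = fs.apply_minmax(fs.fit_minmax(train), test)
        assert out.values.max() > 1.0 or out.values.min() < 0.0

    def test_schema_mismatch_rejected(self, random_table):
        model = fs.fit_minmax(random_table.select_columns([0, 1]))
        with pytest.raises(fs.SchemaError):
            fs.apply_minmax(model, random_table.select_columns([2, 3]))
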