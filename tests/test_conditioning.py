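"""Spatial conditioning: layer-normalized ordinate, partitions, z-scores, loess."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiderk import (
    SynthConfig,
    assign_partition,
    condition_samples,
    layer_normalized_distance,
    loess_fit,
    loess_profile,
    partition_aggregate,
    synth_roi_table,
    to_model_depth,
    zscore_per_patient,
)
from epiderk.exceptions import (
    DegenerateGroupError,
    DegeneratePositionError,
    DomainError,
    EmptyInputError,
    InsufficientDataError,
)


class TestLayerNormalizedDistance:
    @pytest.mark.parametrize(
        "layer,d1,d2,expected",
        [(0, 0, 5, 0.0), (1, 2, 2, 1.5), (2, 3, 1, 2.75)],
    )
    def test_formula(self, layer, d1, d2, expected):
        assert layer_normalized_distance(layer, d1, d2) == pytest.approx(expected)

    def test_degenerate_position(self):
        with pytest.raises(DegeneratePositionError):
            layer_normalized_distance(1, 0.0, 0.0)

    def test_invalid_layer(self):
        with pytest.raises(DomainError):
            layer_normalized_distance(3, 1.0, 1.0)

    @given(
        layer=st.integers(0, 2),
        frac=st.floats(0.0, 1.0, exclude_max=True),
        thickness=st.floats(5.0, 100.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_round_trip_through_boundary_distances(self, layer, frac, thickness):
        """d1, d2 back-computed from u recover u to 1e-9 (generator contract)."""
        u = layer + frac
        d1, d2 = frac * thickness, (1.0 - frac) * thickness
        assert layer_normalized_distance(layer, d1, d2) == pytest.approx(u, abs=1e-9)


class TestModelDepth:
    @pytest.mark.parametrize(
        "u,d", [(0.0, 0.0), (1.0, 1.0), (2.0, 5.0), (3.0, 7.0), (0.5, 0.5), (1.5, 3.0)]
    )
    def test_layer_boundary_mapping(self, u, d):
        assert to_model_depth(u) == pytest.approx(d)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            to_model_depth(3.01)
        with pytest.raises(DomainError):
            to_model_depth(-0.01)

    def test_continuous_strictly_increasing(self):
        u = np.linspace(0, 3, 3001)
        d = to_model_depth(u)
        assert np.all(np.diff(d) > 0)
        assert np.max(np.abs(np.diff(d))) < 0.005  # no jumps at layer boundaries


class TestAssignPartition:
    @pytest.mark.parametrize(
        "u,scheme,part",
        [
            (0.0, "coarse7", 1),
            (3.0, "coarse7", 7),
            (0.99, "fine28", 4),
            (1.0, "fine28", 5),
            (2.999, "fine28", 28),
            (3.0, "fine28", 28),
        ],
    )
    def test_boundaries(self, u, scheme, part):
        assert assign_partition(u, scheme) == part

    @given(u=st.floats(0.0, 3.0))
    @settings(max_examples=300, deadline=None)
    def test_fine_consistent_with_coarse(self, u):
        """Fine partition f always lies inside coarse partition ceil(f/4)."""
        fine = assign_partition(u, "fine28")
        coarse = assign_partition(u, "coarse7")
        assert coarse == -(-fine // 4)

    def test_unknown_scheme(self):
        with pytest.raises(DomainError):
            assign_partition(1.0, "coarse9")


class TestZScore:
    def _table(self, groups):
        rows = []
        for (pat, tgt, comp), vals in groups.items():
            for v in vals:
                rows.append(dict(patient=pat, target=tgt, compartment=comp,
                                 layer_index=0, d1=1.0, d2=1.0, intensity=v))
        return pd.DataFrame(rows)

    def test_closed_form(self):
        df = self._table({("p1", "pERK", "cytoplasm"): [1.0, 2.0, 3.0]})
        z = zscore_per_patient(df)["z"].to_numpy()
        assert z == pytest.approx([-1.0, 0.0, 1.0])

    def test_zero_variance_group(self):
        df = self._table({("p1", "pERK", "cytoplasm"): [2.0, 2.0, 2.0]})
        with pytest.raises(DegenerateGroupError):
            zscore_per_patient(df)

    def test_groups_scored_independently(self):
        df = self._table({
            ("p1", "pERK", "cytoplasm"): [1.0, 5.0, 9.0],
            ("p2", "pERK", "cytoplasm"): [100.0, 200.0, 400.0],
        })
        out = zscore_per_patient(df)
        for _, grp in out.groupby("patient"):
            assert grp["z"].mean() == pytest.approx(0.0, abs=1e-12)
            assert grp["z"].std(ddof=1) == pytest.approx(1.0)

    def test_idempotent(self):
        df = self._table({("p1", "pERK", "cytoplasm"): list(np.arange(20.0))})
        once = zscore_per_patient(df)
        twice = zscore_per_patient(once.assign(intensity=once["z"]))
        assert np.allclose(once["z"], twice["z"], atol=1e-12)


class TestLoess:
    def test_reproduces_line_exactly(self):
        x = np.linspace(0, 1, 50)
        y = 2.0 * x - 1.0
        fit = loess_fit(x, y, x, span=0.3)
        assert np.max(np.abs(fit - y)) < 1e-6

    def test_quadratic_exact_with_full_span(self):
        x = np.linspace(0, 1, 40)
        y = 3.0 * x**2 - x + 0.5
        fit = loess_fit(x, y, x, span=1.0, degree=2)
        assert np.max(np.abs(fit - y)) < 1e-8

    def test_smooths_noise_on_sinusoid(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.uniform(0, 1, 300))
        truth = np.sin(2 * np.pi * x)
        y = truth + rng.normal(0, 0.3, x.size)
        fit = loess_fit(x, y, x, span=0.25)
        assert np.std(fit - truth) < 0.3  # residual vs truth under the noise SD

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            loess_fit([0.0, 1.0], [0.0, 1.0], [0.5], span=0.5)

    def test_profile_stays_within_layer_ranges(self, small_roi_table):
        cond = condition_samples(small_roi_table)
        grp = cond[(cond.target == "pERK") & (cond.compartment == "cytoplasm")]
        sp = loess_profile(grp, span=0.25)
        assert np.all(np.isfinite(sp.fitted))
        assert sp.u.min() >= grp["u"].min() - 1e-12
        assert sp.u.max() <= grp["u"].max() + 1e-12
        assert np.all(np.diff(sp.u) > 0)


class TestPartitionAggregate:
    def _cond(self, u, z):
        return pd.DataFrame({
            "patient": "p1", "target": "pERK", "compartment": "cytoplasm",
            "u": u, "z": z,
        })

    def test_single_sample_single_partition(self):
        profiles = partition_aggregate(self._cond([0.1], [1.0]), scheme="coarse7")
        prof = profiles[0]
        assert prof.counts[0] == 1
        assert prof.values[0] == pytest.approx(1.0)
        assert np.all(prof.counts[1:] == 0)
        assert np.all(np.isnan(prof.values[1:]))

    def test_monotone_trend_gives_increasing_profile(self):
        u = np.linspace(0.001, 2.999, 4000)
        profiles = partition_aggregate(self._cond(u, u), scheme="fine28")
        vals = profiles[0].values
        assert np.all(np.isfinite(vals))
        assert np.all(np.diff(vals) > 0)

    def test_empty_input(self):
        with pytest.raises(EmptyInputError):
            partition_aggregate(self._cond([], []), scheme="coarse7")

    def test_round_trip_from_generator(self, small_roi_table):
        """Generated positions pass through conditioning and recover u exactly."""
        cond = condition_samples(small_roi_table)
        u_direct = layer_normalized_distance(
            cond["layer_index"].to_numpy(),
            cond["d1"].to_numpy(), cond["d2"].to_numpy(),
        )
        assert np.max(np.abs(cond["u"].to_numpy() - u_direct)) < 1e-9
        assert cond["u"].between(0, 3).all()
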